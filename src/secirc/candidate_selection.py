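"""Candidate circRNA funnel: conserved, stage-differential, SE-associated.

The funnel mirrors how a stage-regulated, enhancer-driven circRNA is
nominated from genome-wide catalogs:

1. keep circRNAs conserved across all three species of an ortholog table
   (human/rat/mouse-style, >=95% sequence identity expected of true
   orthologs);
2. keep circRNAs whose mean RPM differs between the two developmental
   stages by at least 1.5-fold in either direction (pseudocount-stabilized);
3. keep SE-circRNAs;
4. rank the survivors by |log2 fold change|, then tissue specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circ_association import CircClass, SE_LABEL
from .io_formats import ExpressionMatrix

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.1  # RPM

# Needleman-Wunsch scoring fixed so identity numbers are reproducible
NW_MATCH = 1
NW_MISMATCH = -1
NW_GAP = -2


@dataclass(frozen=True)
class DECall:
    circ_id: str
    mean_rpm_stage1: float
    mean_rpm_stage2: float
    fold_change: float  # (mean2 + pc) / (mean1 + pc)
    log2fc: float
    is_de: bool


@dataclass(frozen=True)
class CandidateRecord:
    circ_id: str
    label: str
    log2fc: float
    specificity: float
    orthologs: tuple[str, ...]
    rank: int


def fold_change_filter(
    matrix: ExpressionMatrix,
    stage_pair: tuple[str, str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DECall]:
    """Call stage-differential circRNAs on pseudocounted mean-RPM ratios.

    fold_change = (mean_stage2 + pc) / (mean_stage1 + pc); a circRNA is
    differential iff fold_change >= fc_threshold or <= 1/fc_threshold
    (closed thresholds, both directions kept with signed log2fc).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    stage1, stage2 = stage_pair
    by_stage = matrix.mean_by_stage()
    for stage in stage_pair:
        if stage not in by_stage.columns:
            raise ValueError(f"stage {stage!r} absent from expression matrix")
    out: list[DECall] = []
    for circ_id in matrix.circ_ids:
        m1 = float(by_stage.at[circ_id, stage1])
        m2 = float(by_stage.at[circ_id, stage2])
        fc = (m2 + pseudocount) / (m1 + pseudocount)
        is_de = fc >= fc_threshold or fc <= 1.0 / fc_threshold
        out.append(DECall(circ_id, m1, m2, fc, math.log2(fc), is_de))
    return out


def conservation_filter(
    circ_ids: list[str],
    ortholog_table: pd.DataFrame,
    require_all: bool = True,
) -> set[str]:
    """circRNAs present in a complete (all-3-species) ortholog row.

    The first column of the table is the reference-species id matched
    against ``circ_ids``; empty cells mean "no ortholog". With
    ``require_all=False`` one missing species is tolerated.
    """
    if ortholog_table.shape[1] != 3:
        raise ValueError("ortholog table must have exactly 3 species columns")
    universe = set(circ_ids)
    kept: set[str] = set()
    for _, row in ortholog_table.iterrows():
        cells = [str(v).strip() for v in row.tolist()]
        ref = cells[0]
        if ref not in universe:
            continue
        n_present = sum(1 for c in cells if c)
        if (require_all and n_present == 3) or (not require_all and n_present >= 2):
            kept.add(ref)
    return kept


def _nw_align(seq_a: str, seq_b: str) -> tuple[str, str, int]:
    """Global Needleman-Wunsch alignment (match +1 / mismatch -1 / gap -2).

    Traceback ties resolve diagonal > up (gap in b) > left (gap in a),
    making the returned alignment — and hence percent identity —
    deterministic. Returns (aligned_a, aligned_b, score).
    """
    n, m = len(seq_a), len(seq_b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = NW_GAP * np.arange(n + 1)
    score[0, :] = NW_GAP * np.arange(m + 1)
    a_arr = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        match = np.where(a_arr[i - 1] == b_arr, NW_MATCH, NW_MISMATCH)
        diag = score[i - 1, :-1] + match
        up = score[i - 1, 1:] + NW_GAP
        row = score[i, :]
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + NW_GAP)
            row[j] = prev
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = NW_MATCH if seq_a[i - 1] == seq_b[j - 1] else NW_MISMATCH
            if score[i, j] == score[i - 1, j - 1] + s:
                out_a.append(seq_a[i - 1])
                out_b.append(seq_b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + NW_GAP:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(seq_b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


def global_alignment(seq_a: str, seq_b: str) -> tuple[str, str, int]:
    """Public wrapper around the fixed-scoring global aligner."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    return _nw_align(seq_a, seq_b)


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity: matches / alignment columns x 100."""
    aln_a, aln_b, _ = global_alignment(seq_a, seq_b)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return 100.0 * matches / len(aln_a)


def select_candidates(
    classes: list[CircClass],
    de_calls: list[DECall],
    conserved_set: set[str],
    specificity_scores: dict[str, float],
    ortholog_table: pd.DataFrame | None = None,
) -> list[CandidateRecord]:
    """Intersect the three filters and rank the surviving SE-circRNAs.

    Ordering: |log2fc| descending, ties by specificity descending, then
    circ_id ascending; ranks are 1-based.
    """
    se_ids = {c.circ_id for c in classes if c.label == SE_LABEL}
    de_by_id = {d.circ_id: d for d in de_calls if d.is_de}
    orth_by_id: dict[str, tuple[str, ...]] = {}
    if ortholog_table is not None:
        for _, row in ortholog_table.iterrows():
            cells = tuple(str(v).strip() for v in row.tolist())
            if cells[0]:
                orth_by_id[cells[0]] = cells
    chosen = sorted(se_ids & set(de_by_id) & conserved_set)
    records = [
        (
            abs(de_by_id[cid].log2fc),
            specificity_scores.get(cid, 0.0),
            cid,
        )
        for cid in chosen
    ]
    records.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        CandidateRecord(
            circ_id=cid,
            label=SE_LABEL,
            log2fc=de_by_id[cid].log2fc,
            specificity=spec,
            orthologs=orth_by_id.get(cid, (cid, "", "")),
            rank=i,
        )
        for i, (_, spec, cid) in enumerate(records, start=1)
    ]


def write_candidates(candidates: list[CandidateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcirc_id\tlabel\tlog2fc\tspecificity\tortholog_b\tortholog_c\n")
        for c in candidates:
            orth = list(c.orthologs) + ["", ""]
            fh.write(
                f"{c.rank}\t{c.circ_id}\t{c.label}\t{c.log2fc:.6f}\t"
                f"{c.specificity:.6f}\t{orth[1]}\t{orth[2]}\n"
            )
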