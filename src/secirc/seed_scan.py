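"""miRNA seed-site and PWM motif scanning on circular RNA sequences.

A circRNA is covalently closed: the back-splice junction joins the 3' end
of the linear sequence back to its 5' end, so binding sites can straddle
the junction and exist only in the circular form. Scanning therefore runs
on ``seq + seq[:probe_len - 1]`` — long enough that every circular
occurrence of a probe appears exactly once, with positions reported modulo
the circle length.

Seed-site classes are the canonical target-site hierarchy. With miRNA
positions numbered 1..n from its 5' end, the seed core is positions 2-7;
a target site matches the reverse complement of part of the seed region:

    8mer     reverse complement of positions 2-8, followed by an A
    7mer-m8  reverse complement of positions 2-8
    7mer-A1  reverse complement of positions 2-7, followed by an A
    6mer     reverse complement of positions 2-7

Each seed-core occurrence on the circle is reported once with its
strongest class. Sites here are sequence-complementarity calls only; no
hybridization energetics are modelled, so site counts are comparable to,
but not identical with, thermodynamic predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}  # 0 strongest
_SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_SHIFT_TOLERANCE = 2  # nt, conserved-site position slack
DEFAULT_PWM_PSEUDOCOUNT = 0.01


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    circ_id: str
    mirna_id: str
    position: int  # 0-based start of the matched site on the circle
    site_class: str
    spans_junction: bool

    @property
    def length(self) -> int:
        return _SITE_LENGTH[self.site_class]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int
    strand: str
    score: float  # log2-odds bits


def circularize(seq: str, probe_len: int) -> str:
    """Extend a circle's linear form so a probe scan sees every rotation once."""
    if not 1 <= probe_len <= len(seq):
        raise ValueError(f"probe_len {probe_len} outside [1, {len(seq)}]")
    return seq + seq[: probe_len - 1]


def find_seed_sites(
    circ_seq: str,
    mirna_seq: str,
    circ_id: str = "",
    mirna_id: str = "",
) -> list[SeedSite]:
    """All seed-complementary sites of a miRNA on a circular sequence.

    Sites are anchored on occurrences of the 6-nt seed core complement;
    the flanking m8 match and A1 adenosine upgrade the class. Reported
    position is the 0-based circle start of the matched site string for
    the reported class (the 8mer/7mer-m8 site begins one nt before the
    core). Sites crossing the back-splice junction are flagged.
    """
    mirna = mirna_seq.upper().replace("U", "T")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    circ = circ_seq.upper().replace("U", "T")
    L = len(circ)
    core = reverse_complement(mirna[1:7])  # seed positions 2-7
    m8 = reverse_complement(mirna[7])  # complement of position 8
    if L < 6:
        return []
    ext = circ + circ[:8]  # core + flanks never run past this
    best: dict[int, tuple[int, int, str]] = {}  # anchor -> (rank, position, class)
    for j in range(L):
        if ext[j : j + 6] != core:
            continue
        has_m8 = ext[(j - 1) % L] == m8 if j > 0 else circ[L - 1] == m8
        has_a1 = ext[j + 6] == "A"
        if has_m8 and has_a1:
            klass = "8mer"
        elif has_m8:
            klass = "7mer-m8"
        elif has_a1:
            klass = "7mer-A1"
        else:
            klass = "6mer"
        pos = (j - 1) % L if klass in ("8mer", "7mer-m8") else j
        best[j] = (_CLASS_RANK[klass], pos, klass)
    # one site per reported position, strongest class wins
    by_pos: dict[int, tuple[int, str]] = {}
    for rank, pos, klass in best.values():
        if pos not in by_pos or rank < by_pos[pos][0]:
            by_pos[pos] = (rank, klass)
    sites = [
        SeedSite(
            circ_id,
            mirna_id,
            pos,
            klass,
            spans_junction=pos + _SITE_LENGTH[klass] > L,
        )
        for pos, (rank, klass) in by_pos.items()
    ]
    sites.sort(key=lambda s: s.position)
    return sites


def count_conserved_sites(
    site_lists: dict[str, list[SeedSite]],
    sequences: dict[str, str],
    reference: str,
    shift_tolerance: int = DEFAULT_SHIFT_TOLERANCE,
) -> int:
    """Count reference-species sites conserved in every other species.

    Only sites of class 7mer or stronger count. A reference site is
    conserved iff each other species has a >=7mer site whose position,
    mapped through the pairwise global sequence alignment, lies within
    ``shift_tolerance`` nt of the reference site's.
    """
    from .candidate_selection import global_alignment

    if reference not in site_lists or reference not in sequences:
        raise KeyError(f"reference species {reference!r} missing")
    others = [sp for sp in site_lists if sp != reference]
    if not others:
        raise ValueError("need at least 2 species")
    for sp in others:
        if sp not in sequences:
            raise KeyError(f"missing sequence (alignment pair) for {sp!r}")

    def strong(sites: list[SeedSite]) -> list[SeedSite]:
        return [s for s in sites if s.site_class != "6mer"]

    # map reference coordinate -> other-species coordinate via alignment columns
    maps: dict[str, dict[int, int]] = {}
    for sp in others:
        aln_ref, aln_other, _ = global_alignment(sequences[reference], sequences[sp])
        colmap: dict[int, int] = {}
        i = j = 0
        last_j = 0
        for x, y in zip(aln_ref, aln_other):
            if y != "-":
                last_j = j
            if x != "-":
                colmap[i] = last_j
                i += 1
            if y != "-":
                j += 1
        maps[sp] = colmap

    count = 0
    for site in strong(site_lists[reference]):
        ok = True
        for sp in others:
            mapped = maps[sp].get(site.position)
            if mapped is None:
                ok = False
                break
            if not any(
                abs(other.position - mapped) <= shift_tolerance
                for other in strong(site_lists[sp])
            ):
                ok = False
                break
        if ok:
            count += 1
    return count


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def read_jaspar_pwm(path: str | Path) -> np.ndarray:
    """Read a JASPAR-style 4-row count matrix into column-normalized
    probabilities (shape 4 x width, rows A/C/G/T)."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            # tolerate "A [ 1 2 3 ]" and bare "1 2 3"
            cleaned = line.lstrip("ACGTacgt").strip().lstrip("[").rstrip("]")
            rows.append([float(v) for v in cleaned.split()])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 nucleotide rows, got {len(rows)}")
    counts = np.asarray(rows, dtype=float)
    if counts.shape[1] == 0 or np.any(counts < 0):
        raise ValueError(f"{path}: malformed count matrix")
    return counts / counts.sum(axis=0, keepdims=True)


def scan_pwm(
    seq: str,
    pwm: np.ndarray,
    threshold_bits: float,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PWM_PSEUDOCOUNT,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Log2-odds PWM scan of both strands; hits >= threshold, by position.

    ``pwm`` is 4 x width with columns summing to 1 (tolerance 1e-6);
    ``background`` is a length-4 base distribution (default uniform). The
    pseudocount is mixed in before taking log-odds so zero-probability
    cells stay finite. Reverse-strand hits are reported at the forward
    start coordinate of the matched window with strand "-".
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be 4 x width (rows A/C/G/T)")
    if np.any(np.abs(pwm.sum(axis=0) - 1.0) > 1e-6) or np.any(pwm < 0):
        raise ValueError("PWM columns must each sum to 1")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background must be a length-4 distribution")
    probs = (pwm + pseudocount) / (1.0 + 4.0 * pseudocount)
    bg = (background + pseudocount) / (1.0 + 4.0 * pseudocount)
    logodds = np.log2(probs) - np.log2(bg)[:, None]

    width = pwm.shape[1]
    seq = seq.upper().replace("U", "T")
    hits: list[MotifHit] = []
    for strand in "+-":
        target = seq if strand == "+" else reverse_complement(seq)
        idx = np.array([_BASE_INDEX.get(b, -1) for b in target])
        for start in range(len(seq) - width + 1):
            window = idx[start : start + width]
            if np.any(window < 0):  # N bases never score
                continue
            score = float(logodds[window, np.arange(width)].sum())
            if score >= threshold_bits:
                pos = start if strand == "+" else len(seq) - width - start
                hits.append(MotifHit(sequence_id, pos, strand, score))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_all_seed_sites(
    circ_seqs: dict[str, str], mirna_seqs: dict[str, str]
) -> list[SeedSite]:
    """Seed scan of every circRNA x miRNA pair, flattened and ordered."""
    out: list[SeedSite] = []
    for circ_id in sorted(circ_seqs):
        for mirna_id in sorted(mirna_seqs):
            out.extend(
                find_seed_sites(circ_seqs[circ_id], mirna_seqs[mirna_id], circ_id, mirna_id)
            )
    return out


def write_sites(sites: list[SeedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tmirna_id\tposition\tsite_class\tspans_junction\n")
        for s in sites:
            fh.write(
                f"{s.circ_id}\t{s.mirna_id}\t{s.position}\t{s.site_class}\t{int(s.spans_junction)}\n"
            )
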