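"""Synthetic inputs with a planted ground truth for every pipeline stage.

The generator emulates the statistical shape of the study's inputs — an
H3K27ac enhancer catalog with a heavy-tailed signal distribution and a
small class of clustered, very-high-signal regions (super-enhancers);
circRNA loci whose promoters sit near those clusters; a tissue x stage
RPM expression matrix in which SE-circRNAs are more abundant and more
tissue-restricted, with planted fold changes between an embryonic and an
adult stage; a three-species ortholog table; and circular sequences
carrying planted miRNA seed sites, at least one of which straddles the
back-splice junction. A :class:`TruthLedger` records everything planted so
downstream calls can be checked exactly.

Placement geometry guarantees clean classification on noiseless settings:
planted SE clusters keep a >50 kb buffer from every circRNA promoter
except their own planted SE-circRNA, typical peaks are spaced beyond the
stitching window so each forms its own stitched region, and "other"
circRNAs sit >50 kb from any peak.

Randomness: one integer seed; each data facet draws from its own
``numpy.random.default_rng([seed, facet_offset])`` sub-stream, so adding a
facet never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    Interval,
    write_bed,
    write_expression_matrix,
    write_fasta,
    write_json,
)
from .seed_scan import reverse_complement

import pandas as pd

_TISSUE_NAMES = ["heart", "brain", "lung", "colon", "stomach"]
_STREAM = {  # fixed sub-stream offsets off the global seed
    "layout": 1,
    "signal": 2,
    "expression": 3,
    "orthologs": 4,
    "sequence": 5,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data; see module docstring."""

    n_chromosomes: int = 10
    chrom_length: int = 2_500_000
    n_enhancer_peaks: int = 500  # typical (non-planted) peaks
    n_planted_SE_clusters: int = 25
    SE_signal_multiplier: float = 20.0
    n_circRNAs: int = 200
    n_tissues: int = 5
    stages: tuple[str, str] = ("embryonic", "adult")
    planted_DE_fold: float = 4.0
    rpm_noise_cv: float = 0.0
    n_planted_candidates: int = 5
    n_replicates: int = 3
    stitch_window: int = 12_500
    assignment_window: int = 50_000
    seed: int = 42

    def validate(self) -> None:
        counts = (
            self.n_chromosomes,
            self.n_enhancer_peaks,
            self.n_planted_SE_clusters,
            self.n_circRNAs,
            self.n_tissues,
            self.n_planted_candidates,
            self.n_replicates,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.SE_signal_multiplier <= 1:
            raise ValueError("SE_signal_multiplier must be > 1")
        if self.planted_DE_fold < 1:
            raise ValueError("planted_DE_fold must be >= 1")
        if len(self.stages) != 2:
            raise ValueError("exactly two stages required for the DE design")
        if self.chrom_length <= 10 * self.stitch_window:
            raise ValueError("chrom_length must exceed 10x the stitching window")
        if self.n_circRNAs == 0 and self.n_planted_candidates > 0:
            raise ValueError("cannot plant candidates without circRNAs")
        if self.n_planted_candidates > self.n_planted_SE_clusters:
            raise ValueError("candidates cannot exceed planted SE clusters")
        if self.n_circRNAs < self.n_planted_SE_clusters:
            raise ValueError("need at least one circRNA per planted SE cluster")


@dataclass
class PlantedSeedSite:
    circ_id: str
    mirna_id: str
    position: int
    site_class: str


@dataclass
class TruthLedger:
    """Everything the generator planted, for exact downstream checks."""

    planted_SE_region_ids: list[str] = field(default_factory=list)
    planted_SE_regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    planted_SE_circ_ids: list[str] = field(default_factory=list)
    planted_DE_circ_ids: list[str] = field(default_factory=list)
    planted_candidate_ids: list[str] = field(default_factory=list)
    planted_seed_sites: list[PlantedSeedSite] = field(default_factory=list)

    def to_json(self) -> dict:
        d = asdict(self)
        d["planted_SE_regions"] = {k: list(v) for k, v in self.planted_SE_regions.items()}
        return d

    @classmethod
    def from_json(cls, d: dict) -> "TruthLedger":
        return cls(
            planted_SE_region_ids=list(d["planted_SE_region_ids"]),
            planted_SE_regions={k: tuple(v) for k, v in d["planted_SE_regions"].items()},
            planted_SE_circ_ids=list(d["planted_SE_circ_ids"]),
            planted_DE_circ_ids=list(d["planted_DE_circ_ids"]),
            planted_candidate_ids=list(d["planted_candidate_ids"]),
            planted_seed_sites=[PlantedSeedSite(**s) for s in d["planted_seed_sites"]],
        )


@dataclass
class _Circ:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    role: str  # "se" | "te" | "other"


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stream]])


# ---------------------------------------------------------------------------
# genome layout: peaks, clusters, circRNA loci
# ---------------------------------------------------------------------------

def _build_layout(config: SynthConfig):
    rng = _rng(config, "layout")
    n_se_circs = config.n_planted_SE_clusters
    n_free = config.n_circRNAs - n_se_circs
    n_other = n_free // 3
    n_te = n_free - n_other

    peaks: list[Interval] = []
    circs: list[_Circ] = []
    ledger = TruthLedger()
    peak_counter = 0
    circ_counter = 0

    def new_circ_id() -> str:
        nonlocal circ_counter
        circ_counter += 1
        return f"mmu_circ_{circ_counter:04d}"

    # entity stream: SE clusters + typical peaks (some carrying a TE circ)
    entities = (
        ["cluster"] * config.n_planted_SE_clusters
        + ["typical_circ"] * n_te
        + ["typical"] * (config.n_enhancer_peaks - n_te)
    )
    if config.n_enhancer_peaks < n_te:
        raise ValueError("more TE circRNAs than typical peaks available")
    entities = [entities[i] for i in rng.permutation(len(entities))]

    chrom_idx = 0
    cursor = 10_000
    buffer_after_cluster = 70_000  # keeps later promoters >50 kb from SEs
    buffer_after_typical = 15_000  # > stitch window: one stitched region each
    cluster_lead_in = 55_000  # keeps earlier promoters >50 kb from SEs

    def advance(extent: int, buffer: int, lead: int = 0) -> tuple[str, int] | None:
        """Reserve [cursor+lead, cursor+lead+extent) on the current chromosome."""
        nonlocal chrom_idx, cursor
        while chrom_idx < config.n_chromosomes:
            if cursor + lead + extent + buffer < config.chrom_length:
                chrom = f"chr{chrom_idx + 1}"
                start = cursor + lead
                cursor += lead + extent + buffer
                return chrom, start
            chrom_idx += 1
            cursor = 10_000
        return None

    cluster_n = 0
    for kind in entities:
        if kind == "cluster":
            n_member = int(rng.integers(3, 6))
            widths = rng.integers(600, 1500, size=n_member)
            gaps = rng.integers(500, 1800, size=n_member - 1) if n_member > 1 else []
            span = int(widths.sum() + sum(gaps))
            circ_gap = int(rng.integers(3_000, 15_000))
            circ_len = int(rng.integers(2_000, 9_000))
            extent = span + circ_gap + circ_len + 1_000
            slot = advance(extent, buffer_after_cluster, lead=cluster_lead_in)
            if slot is None:
                raise ValueError("chromosomes too short for the requested entities")
            chrom, pos = slot
            cluster_id = f"SE_cluster_{cluster_n:03d}"
            cluster_start = pos
            for i, w in enumerate(widths):
                peak_counter += 1
                peaks.append(
                    Interval(chrom, pos, pos + int(w), f"peak_{peak_counter:05d}")
                )
                pos += int(w) + (int(gaps[i]) if i < n_member - 1 else 0)
            cluster_end = peaks[-1].end
            ledger.planted_SE_region_ids.append(cluster_id)
            ledger.planted_SE_regions[cluster_id] = (chrom, cluster_start, cluster_end)
            # planted SE-circRNA: promoter (5' end) within the window
            cid = new_circ_id()
            promoter = cluster_end + circ_gap
            strand = "+" if rng.random() < 0.5 else "-"
            # '-' promoters anchor at span.end, so the span sits upstream
            if strand == "+":
                span_start, span_end = promoter, promoter + circ_len
            else:
                span_start, span_end = promoter - circ_len, promoter
            circs.append(_Circ(cid, chrom, span_start, span_end, strand, "se"))
            ledger.planted_SE_circ_ids.append(cid)
            cluster_n += 1
        else:
            width = int(rng.integers(600, 2_000))
            if kind == "typical_circ":
                circ_gap = int(rng.integers(2_000, 30_000))
                circ_len = int(rng.integers(2_000, 9_000))
                extent = width + circ_gap + circ_len + 1_000
            else:
                extent = width
            slot = advance(extent, buffer_after_typical)
            if slot is None:
                raise ValueError("chromosomes too short for the requested entities")
            chrom, pos = slot
            peak_counter += 1
            peaks.append(Interval(chrom, pos, pos + width, f"peak_{peak_counter:05d}"))
            if kind == "typical_circ":
                cid = new_circ_id()
                promoter = pos + width + circ_gap
                circs.append(_Circ(cid, chrom, promoter, promoter + circ_len, "+", "te"))

    # "other" circRNAs: packed blocks >50 kb clear of any peak
    placed_other = 0
    while placed_other < n_other:
        circ_len = int(rng.integers(2_000, 9_000))
        slot = advance(55_000 + circ_len, 0)
        if slot is None:
            raise ValueError("chromosomes too short for the requested circRNAs")
        chrom, pos = slot
        start = pos + 55_000
        cid = new_circ_id()
        circs.append(_Circ(cid, chrom, start, start + circ_len, "+", "other"))
        # pack siblings into the same cleared block while room remains
        while placed_other + 1 < n_other:
            nxt = int(rng.integers(2_000, 9_000))
            if cursor + nxt + 2_000 + 55_000 >= config.chrom_length:
                break
            s = cursor + 2_000
            cursor = s + nxt
            cid = new_circ_id()
            circs.append(_Circ(cid, chrom, s, s + nxt, "+", "other"))
            placed_other += 1
        cursor += 55_000
        placed_other += 1

    return peaks, circs, ledger


# ---------------------------------------------------------------------------
# signal, expression, orthologs, sequences
# ---------------------------------------------------------------------------

def _assign_signal(config: SynthConfig, peaks: list[Interval], ledger: TruthLedger):
    rng = _rng(config, "signal")
    cluster_spans = list(ledger.planted_SE_regions.values())

    def in_cluster(p: Interval) -> bool:
        return any(c == p.chrom and s <= p.start and p.end <= e for c, s, e in cluster_spans)

    out: list[Interval] = []
    for p in peaks:
        draw = float(rng.lognormal(mean=0.0, sigma=1.0))
        if in_cluster(p):
            sig = config.SE_signal_multiplier * (1.0 + draw)
        else:
            sig = draw
        out.append(Interval(p.chrom, p.start, p.end, p.id, p.strand, sig))
    return out


def _plant_de(config: SynthConfig, circs: list[_Circ], ledger: TruthLedger) -> dict[str, float]:
    """Pick candidates/decoys; return per-circ stage2/stage1 fold ratios."""
    se_ids = list(ledger.planted_SE_circ_ids)
    non_se_ids = [c.id for c in circs if c.role != "se"]
    candidates = se_ids[: config.n_planted_candidates]
    n_se_decoys = min(5, len(se_ids) - len(candidates))
    se_decoys = se_ids[len(candidates) : len(candidates) + n_se_decoys]
    n_other_de = min(10, len(non_se_ids))
    other_de = non_se_ids[:n_other_de]

    ledger.planted_candidate_ids = sorted(candidates)
    de_ids = candidates + se_decoys + other_de
    ledger.planted_DE_circ_ids = sorted(de_ids)

    ratios: dict[str, float] = {}
    for i, cid in enumerate(de_ids):
        up = i % 2 == 0
        ratios[cid] = config.planted_DE_fold if up else 1.0 / config.planted_DE_fold
    return ratios


def _build_expression(
    config: SynthConfig, circs: list[_Circ], ratios: dict[str, float]
) -> ExpressionMatrix:
    rng = _rng(config, "expression")
    tissues = (_TISSUE_NAMES + [f"tissue{i}" for i in range(6, config.n_tissues + 1)])[
        : config.n_tissues
    ]
    stage1, stage2 = config.stages
    samples = [
        f"{t}:{s}:{r + 1}"
        for t in tissues
        for s in (stage1, stage2)
        for r in range(config.n_replicates)
    ]
    base_mu = {"se": math.log(20.0), "te": math.log(5.0), "other": math.log(2.0)}
    home_weight = {"se": 0.9, "te": 0.45, "other": 0.35}
    rows = []
    for circ in circs:
        base = float(np.exp(rng.normal(base_mu[circ.role], 0.5)))
        home = int(rng.integers(0, len(tissues)))
        w = home_weight[circ.role]
        profile = np.full(len(tissues), (1.0 - w) / max(len(tissues) - 1, 1))
        profile[home] = w if len(tissues) > 1 else 1.0
        ratio = ratios.get(circ.id, 1.0)
        # stage factors with geometric mean 1 keep overall abundance stable
        f1, f2 = 1.0 / math.sqrt(ratio), math.sqrt(ratio)
        row = []
        for t_idx in range(len(tissues)):
            for s_idx, f in enumerate((f1, f2)):
                for _ in range(config.n_replicates):
                    value = base * profile[t_idx] * f
                    if config.rpm_noise_cv > 0:
                        sigma = math.sqrt(math.log(1.0 + config.rpm_noise_cv**2))
                        value *= float(rng.lognormal(-sigma**2 / 2.0, sigma))
                    row.append(value)
        rows.append(row)
    frame = pd.DataFrame(rows, index=[c.id for c in circs], columns=samples, dtype=float)
    return ExpressionMatrix(frame)


def _build_orthologs(config: SynthConfig, circs: list[_Circ], ledger: TruthLedger) -> pd.DataFrame:
    rng = _rng(config, "orthologs")
    candidates = set(ledger.planted_candidate_ids)
    de_ids = set(ledger.planted_DE_circ_ids)
    se_decoys = (de_ids & set(ledger.planted_SE_circ_ids)) - candidates
    rows = []
    for circ in circs:
        num = circ.id.split("_")[-1]
        rno, hsa = f"rno_circ_{num}", f"hsa_circ_{num}"
        if circ.id in candidates:
            rows.append((circ.id, rno, hsa))
        elif circ.id in se_decoys:
            rows.append((circ.id, rno, ""))  # missing human ortholog
        elif rng.random() < 0.6:
            rows.append((circ.id, rno, hsa))
        elif rng.random() < 0.5:
            rows.append((circ.id, "", hsa))
    return pd.DataFrame(rows, columns=["mmu_id", "rno_id", "hsa_id"])


# --- sequences with planted, scrubbed seed sites ---------------------------

_PLANT_PLAN = (  # (site class, placement) per candidate, mirna mir_syn_1
    ("7mer-m8", "junction"),
    ("8mer", "interior"),
    ("7mer-A1", "interior"),
)


def _site_string(mirna: str, site_class: str) -> str:
    core = reverse_complement(mirna[1:7])
    m8 = reverse_complement(mirna[7])
    if site_class == "8mer":
        return m8 + core + "A"
    if site_class == "7mer-m8":
        return m8 + core
    if site_class == "7mer-A1":
        return core + "A"
    return core


def _make_mirnas(rng: np.random.Generator, n: int = 3) -> dict[str, str]:
    """Synthetic 22-nt miRNAs whose seed-site strings share no 6-mer."""
    bases = "ACGT"
    while True:
        mirnas = {
            f"mir_syn_{i + 1}": "".join(rng.choice(list(bases), size=22))
            for i in range(n)
        }
        kmers: list[set[str]] = []
        for seq in mirnas.values():
            s = _site_string(seq, "8mer")
            kmers.append({s[i : i + 6] for i in range(len(s) - 5)})
        clash = any(kmers[i] & kmers[j] for i in range(n) for j in range(i + 1, n))
        if not clash:
            return mirnas


def _scrub(seq: list[str], protected: set[int], mirnas: dict[str, str], rng) -> bool:
    """Mutate stray seed-core matches (circularly) outside protected spans.

    Returns False when a stray match lies entirely inside protected bases
    (cannot be removed) or scrubbing fails to converge; callers then
    redraw the background sequence.
    """
    L = len(seq)
    cores = [reverse_complement(m[1:7]) for m in mirnas.values()]
    for _ in range(50):
        dirty = False
        text = "".join(seq) + "".join(seq[:5])
        for core in cores:
            start = 0
            while True:
                j = text.find(core, start)
                if j == -1 or j >= L:
                    break
                window = [(j + k) % L for k in range(6)]
                free = [p for p in window if p not in protected]
                if free:
                    p = free[len(free) // 2]
                    current = seq[p]
                    seq[p] = str(rng.choice([b for b in "ACGT" if b != current]))
                    dirty = True
                # fully protected matches are either planted (fine) or an
                # unfixable clash; the caller's plan check decides which
                start = j + 1
        if not dirty:
            return True
    return False


def _plant_sites(
    seq: list[str], mirna: str, plan, L: int
) -> tuple[set[int], list[tuple[int, str]]]:
    """Write the planted site strings into ``seq``; returns (protected
    positions, [(position, class)])."""
    m8 = reverse_complement(mirna[7])
    protected: set[int] = set()
    planted: list[tuple[int, str]] = []
    for k, (site_class, placement) in enumerate(plan):
        site = _site_string(mirna, site_class)
        pos = L - 4 if placement == "junction" else 30 + k * 40
        for i, base in enumerate(site):
            seq[(pos + i) % L] = base
        # pin the flanks so the class is exactly as recorded
        before, after = (pos - 1) % L, (pos + len(site)) % L
        if site_class in ("7mer-A1", "6mer") and seq[before] == m8:
            seq[before] = "C" if m8 != "C" else "G"
        if site_class in ("7mer-m8", "6mer") and seq[after] == "A":
            seq[after] = "C"
        protected |= {(pos - 1 + i) % L for i in range(len(site) + 2)}
        planted.append((pos, site_class))
    return protected, planted


def _sites_match_plan(seq: str, mirnas: dict[str, str], mir1_id: str, planted) -> bool:
    from .seed_scan import find_seed_sites

    found = []
    for mid, mseq in mirnas.items():
        for s in find_seed_sites(seq, mseq, "x", mid):
            found.append((mid, s.position, s.site_class))
    expected = sorted((mir1_id, pos, cls) for pos, cls in planted)
    return sorted(found) == expected


def _build_sequences(config: SynthConfig, circs: list[_Circ], ledger: TruthLedger):
    rng = _rng(config, "sequence")
    mirnas = _make_mirnas(rng)
    mir1_id = "mir_syn_1"
    candidates = set(ledger.planted_candidate_ids)

    circ_seqs: dict[str, str] = {}
    ortho_seqs: dict[str, str] = {}
    for circ in circs:
        for _attempt in range(50):
            L = int(rng.integers(300, 600))
            seq = list("".join(rng.choice(list("ACGT"), size=L)))
            protected: set[int] = set()
            planted: list[tuple[int, str]] = []
            if circ.id in candidates:
                protected, planted = _plant_sites(seq, mirnas[mir1_id], _PLANT_PLAN, L)
            if not _scrub(seq, protected, mirnas, rng):
                continue
            text = "".join(seq)
            if not _sites_match_plan(text, mirnas, mir1_id, planted):
                continue
            if circ.id in candidates:
                # pseudo-species orthologs: ~2% substitutions off planted sites
                num = circ.id.split("_")[-1]
                orthos: dict[str, str] = {}
                ok = True
                for prefix in ("rno", "hsa"):
                    for _otry in range(25):
                        ortho = list(text)
                        n_sub = max(1, int(round(0.02 * L)))
                        free = [p for p in range(L) if p not in protected]
                        subs = rng.choice(free, size=min(n_sub, len(free)), replace=False)
                        for p in subs:
                            ortho[p] = str(rng.choice([b for b in "ACGT" if b != ortho[p]]))
                        if _scrub(ortho, protected, mirnas, rng) and _sites_match_plan(
                            "".join(ortho), mirnas, mir1_id, planted
                        ):
                            orthos[f"{prefix}_circ_{num}"] = "".join(ortho)
                            break
                    else:
                        ok = False
                        break
                if not ok:
                    continue
                ortho_seqs.update(orthos)
            circ_seqs[circ.id] = text
            for pos, cls in planted:
                ledger.planted_seed_sites.append(PlantedSeedSite(circ.id, mir1_id, pos, cls))
            break
        else:
            raise RuntimeError(f"could not build a clean sequence for {circ.id}")
    return circ_seqs, ortho_seqs, mirnas


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig, out_dir: str | Path) -> tuple[dict[str, Path], TruthLedger]:
    """Write all synthetic inputs into ``out_dir`` and return the ledger.

    Outputs: ``peaks.bed`` (BED6 + signal column), ``circs.bed``,
    ``expression.tsv``, ``orthologs.tsv``, ``circ_sequences.fa``,
    ``ortholog_sequences.fa``, ``mirnas.fa``, ``truth_ledger.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    peaks, circs, ledger = _build_layout(config)
    peaks = _assign_signal(config, peaks, ledger)
    ratios = _plant_de(config, circs, ledger)
    matrix = _build_expression(config, circs, ratios)
    orthologs = _build_orthologs(config, circs, ledger)
    circ_seqs, ortho_seqs, mirnas = _build_sequences(config, circs, ledger)

    paths = {name: out_dir / fname for name, fname in [
        ("peaks", "peaks.bed"),
        ("circs", "circs.bed"),
        ("expression", "expression.tsv"),
        ("orthologs", "orthologs.tsv"),
        ("circ_fasta", "circ_sequences.fa"),
        ("ortholog_fasta", "ortholog_sequences.fa"),
        ("mirna_fasta", "mirnas.fa"),
        ("ledger", "truth_ledger.json"),
    ]}
    write_bed(peaks, paths["peaks"])
    write_bed(
        [Interval(c.chrom, c.start, c.end, c.id, c.strand) for c in circs],
        paths["circs"],
    )
    write_expression_matrix(matrix, paths["expression"])
    orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
    write_fasta(circ_seqs, paths["circ_fasta"])
    write_fasta(ortho_seqs, paths["ortholog_fasta"])
    write_fasta(mirnas, paths["mirna_fasta"])
    write_json(ledger.to_json(), paths["ledger"])
    return paths, ledger
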