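"""Enhancer-to-circRNA-promoter assignment and SE-/TE-circRNA labelling.

Each called enhancer region (super or typical) is assigned to the single
circRNA whose promoter point is most proximal, provided the distance is
within an assignment window (default 50 kb). A circRNA with at least one
super-enhancer assignment is an SE-circRNA; with only typical assignments a
TE-circRNA; with none, "other". The promoter of a circRNA is its host-gene
TSS when known, otherwise the 5' end of the back-spliced span.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io_formats import Interval
from .se_calling import SECall

DEFAULT_ASSIGNMENT_WINDOW = 50_000

SE_LABEL = "SE-circRNA"
TE_LABEL = "TE-circRNA"
OTHER_LABEL = "other"


@dataclass(frozen=True)
class CircRNA:
    """A circRNA locus: back-splice span plus an optional host-gene TSS."""

    id: str
    span: Interval
    host_gene: str | None = None
    host_tss: int | None = None
    sequence_id: str | None = None

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"circRNA {self.id} needs an explicit +/- strand")


@dataclass(frozen=True)
class Assignment:
    enhancer_id: str
    circ_id: str
    distance: int
    enhancer_class: str  # "super" | "typical"


@dataclass(frozen=True)
class CircClass:
    circ_id: str
    label: str
    nearest_se_id: str | None = None
    distance: int | None = None


def promoter_point(circ: CircRNA) -> int:
    """Promoter anchor: host TSS if known, else the 5' end of the span."""
    if circ.host_tss is not None:
        return circ.host_tss
    return circ.span.start if circ.span.strand == "+" else circ.span.end


def assign_enhancers(
    enhancers: list[SECall],
    circs: list[CircRNA],
    window: int = DEFAULT_ASSIGNMENT_WINDOW,
) -> list[Assignment]:
    """Assign each enhancer to its most proximal circRNA promoter.

    Distance is point-to-region: 0 if the promoter falls inside the region,
    else the bp gap to the nearest boundary. Enhancers with no promoter
    within ``window`` are dropped; equidistant promoters resolve to the
    lexicographically smallest circ id.
    """
    promoters: dict[str, list[tuple[int, str]]] = {}
    for circ in circs:
        promoters.setdefault(circ.span.chrom, []).append((promoter_point(circ), circ.id))
    for entries in promoters.values():
        entries.sort()

    out: list[Assignment] = []
    for call in enhancers:
        region = call.region.interval
        best: tuple[int, str] | None = None
        for point, circ_id in promoters.get(region.chrom, ()):
            if point < region.start - window:
                continue
            if point > region.end + window:
                break
            d = _point_region_distance(point, region)
            if d <= window and (best is None or (d, circ_id) < best):
                best = (d, circ_id)
        if best is not None:
            klass = "super" if call.is_super else "typical"
            out.append(Assignment(region.id, best[1], best[0], klass))
    return out


def _point_region_distance(point: int, region: Interval) -> int:
    if region.start <= point < region.end:
        return 0
    return region.start - point if point < region.start else point - region.end + 1


def classify_circs(assignments: list[Assignment], circs: list[CircRNA]) -> list[CircClass]:
    """Label every circRNA as SE-circRNA / TE-circRNA / other."""
    super_hits: dict[str, tuple[int, str]] = {}
    typical: set[str] = set()
    for a in assignments:
        if a.enhancer_class == "super":
            prev = super_hits.get(a.circ_id)
            if prev is None or (a.distance, a.enhancer_id) < prev:
                super_hits[a.circ_id] = (a.distance, a.enhancer_id)
        else:
            typical.add(a.circ_id)
    out: list[CircClass] = []
    for circ in circs:
        if circ.id in super_hits:
            d, eid = super_hits[circ.id]
            out.append(CircClass(circ.id, SE_LABEL, nearest_se_id=eid, distance=d))
        elif circ.id in typical:
            out.append(CircClass(circ.id, TE_LABEL))
        else:
            out.append(CircClass(circ.id, OTHER_LABEL))
    return out


def circs_from_bed(intervals: list[Interval]) -> list[CircRNA]:
    return [CircRNA(iv.id, iv) for iv in intervals]


def write_classes(classes: list[CircClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tlabel\tnearest_se_id\tdistance\n")
        for c in classes:
            fh.write(
                f"{c.circ_id}\t{c.label}\t{c.nearest_se_id or ''}\t"
                f"{'' if c.distance is None else c.distance}\n"
            )


def read_classes(path: str | Path) -> list[CircClass]:
    out: list[CircClass] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("circ_id"):
            raise ValueError(f"{path}: missing classes header")
        for line in fh:
            if not line.strip():
                continue
            circ_id, label, se_id, dist = line.rstrip("\n").split("\t")
            out.append(
                CircClass(circ_id, label, se_id or None, int(dist) if dist else None)
            )
    return out
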