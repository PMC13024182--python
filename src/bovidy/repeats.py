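"""Repeat-landscape composition tables and cross-species comparison.

Aggregates repeat annotations into the canonical composition ledger of a
chromosome: Class I retrotransposons (LINE, SINE, LTR, Penelope), Class II
DNA transposons (cut-and-paste DNA elements plus rolling-circle Helitrons),
and the residual class, each as total bp, percentage of the repeat total,
and percentage of the chromosome. Percentages are computed on unrounded
fractions and rounded half-up to two decimals only at presentation, so
derived quantities (percentage-point deltas, fold changes) are exact.

Also labels self-similarity blocks from triangular dot-plot summaries:
HS (high self-similarity, >95% identity) and MS (medium, 90-95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from ._util import round_half_up

SUPERFAMILIES = ("LINE", "SINE", "LTR", "Penelope", "DNA", "Helitron", "other")
CLASS_OF = {"LINE": "ClassI", "SINE": "ClassI", "LTR": "ClassI",
            "Penelope": "ClassI", "DNA": "ClassII", "Helitron": "ClassII",
            "other": "Rest"}
CLASSES = ("ClassI", "ClassII", "Rest")


class RepeatError(ValueError):
    pass


@dataclass
class RepeatRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    superfamily: str  # one of SUPERFAMILIES
    family: str = ""

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise RepeatError(f"unknown superfamily {self.superfamily!r}")
        if self.end < self.start:
            raise RepeatError("end < start")

    @property
    def repeat_class(self) -> str:
        return CLASS_OF[self.superfamily]


@dataclass
class CompositionTable:
    chrom_len: int
    total_bp: dict[str, int]  # per superfamily and per class, plus "Repeats"
    copy_count: dict[str, int] = field(default_factory=dict)
    regions: dict[str, int] = field(default_factory=dict)  # telomere, PAR, ...

    def pct_of_repeats(self, key: str, digits: int = 2) -> float:
        total = self.total_bp["Repeats"]
        if total == 0:
            return 0.0
        return round_half_up((100 * self.total_bp.get(key, 0), total), digits)

    def pct_of_chromosome(self, key: str, digits: int = 2) -> float:
        return round_half_up((100 * self.total_bp.get(key, 0), self.chrom_len), digits)

    def fraction_of_repeats(self, key: str) -> Fraction:
        total = self.total_bp["Repeats"]
        return Fraction(self.total_bp.get(key, 0), total) if total else Fraction(0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("Repeats",) + CLASSES + SUPERFAMILIES:
            if key not in self.total_bp:
                continue
            rows.append({"category": key, "total_bp": self.total_bp[key],
                         "pct_of_repeats": self.pct_of_repeats(key),
                         "pct_of_chromosome": self.pct_of_chromosome(key),
                         "copies": self.copy_count.get(key, 0)})
        return pd.DataFrame(rows)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def aggregate(records: list[RepeatRecord], chrom_len: int,
              regions: dict[str, int] | None = None) -> CompositionTable:
    """Sum repeat bp per superfamily and class over ``records``.

    Overlapping records within a superfamily are merged before summing, so
    each base is counted once per superfamily. Records beyond ``chrom_len``
    raise.
    """
    by_sf: dict[str, list[tuple[int, int]]] = {}
    counts: dict[str, int] = {}
    for r in records:
        if r.end > chrom_len:
            raise RepeatError(f"record {r.start}-{r.end} beyond chrom_len {chrom_len}")
        by_sf.setdefault(r.superfamily, []).append((r.start, r.end))
        counts[r.superfamily] = counts.get(r.superfamily, 0) + 1
    total_bp: dict[str, int] = {c: 0 for c in CLASSES}
    for sf, ivs in by_sf.items():
        bp = sum(e - s + 1 for s, e in _merge_intervals(ivs))
        total_bp[sf] = bp
        total_bp[CLASS_OF[sf]] += bp
        counts[CLASS_OF[sf]] = counts.get(CLASS_OF[sf], 0) + counts[sf]
    total_bp["Repeats"] = sum(total_bp[c] for c in CLASSES)
    return CompositionTable(chrom_len=chrom_len, total_bp=total_bp,
                            copy_count=counts, regions=dict(regions or {}))


def from_lengths(lengths: dict[str, int], chrom_len: int,
                 copy_count: dict[str, int] | None = None,
                 regions: dict[str, int] | None = None) -> CompositionTable:
    """Build a CompositionTable directly from per-superfamily bp totals
    (e.g. a published table's printed lengths)."""
    total_bp: dict[str, int] = {c: 0 for c in CLASSES}
    for sf, bp in lengths.items():
        if sf not in SUPERFAMILIES:
            raise RepeatError(f"unknown superfamily {sf!r}")
        total_bp[sf] = bp
        total_bp[CLASS_OF[sf]] += bp
    total_bp["Repeats"] = sum(total_bp[c] for c in CLASSES)
    return CompositionTable(chrom_len=chrom_len, total_bp=total_bp,
                            copy_count=dict(copy_count or {}),
                            regions=dict(regions or {}))


def compare_species(a: CompositionTable, b: CompositionTable) -> dict:
    """Deltas between two composition tables.

    Percentage-point deltas are computed on unrounded fractions of the
    repeat total and rounded at the end; bp differences and fold changes
    (larger/smaller, with a direction flag) come from the raw lengths.
    """
    keys = set(a.total_bp) | set(b.total_bp)
    if set(a.total_bp) != set(b.total_bp):
        missing = keys - (set(a.total_bp) & set(b.total_bp))
        raise RepeatError(f"schema mismatch between tables: {sorted(missing)}")
    out: dict[str, dict] = {}
    for key in sorted(keys - {"Repeats"}):
        fa = a.fraction_of_repeats(key)
        fb = b.fraction_of_repeats(key)
        bp_a, bp_b = a.total_bp[key], b.total_bp[key]
        if bp_a == bp_b == 0:
            fold, direction = 1.0, "equal"
        elif min(bp_a, bp_b) == 0:
            fold, direction = float("inf"), ("a" if bp_a else "b")
        else:
            fold = round_half_up((max(bp_a, bp_b), min(bp_a, bp_b)), 2)
            direction = "equal" if bp_a == bp_b else ("a" if bp_a > bp_b else "b")
        out[key] = {
            "pp_delta": round_half_up((100 * (fa - fb).numerator, (fa - fb).denominator), 2)
            if (fa - fb).denominator else 0.0,
            "bp_delta": bp_a - bp_b,
            "fold": fold,
            "larger": direction,
        }
    regions = set(a.regions) & set(b.regions)
    out["regions"] = {k: {"bp_delta": a.regions[k] - b.regions[k]} for k in sorted(regions)}
    return out


def region_fractions(ledger: dict[str, int], chrom_len: int,
                     genome_len: int | None = None) -> dict[str, float]:
    """Region lengths as percentages: each region over the chromosome, and
    (when ``genome_len`` is given) the chromosome over the genome."""
    if chrom_len <= 0:
        raise RepeatError("chrom_len must be positive")
    out = {}
    for name, length in ledger.items():
        if length > chrom_len:
            raise RepeatError(f"region {name} ({length} bp) longer than chromosome")
        out[f"{name}_pct_of_chromosome"] = round_half_up((100 * length, chrom_len), 2)
    if genome_len:
        out["chromosome_pct_of_genome"] = round_half_up((100 * chrom_len, genome_len), 2)
    return out


# ---------------------------------------------------------------------------
# self-similarity blocks


@dataclass
class SelfSimBlock:
    start: int
    end: int
    identity: float  # mean identity in [0, 1]
    label: str = ""


def label_selfsim_blocks(blocks: list[SelfSimBlock] | list[tuple[int, int, float]],
                         non_par_len: int | None = None,
                         hs_threshold: float = 0.95,
                         ms_low: float = 0.90) -> dict:
    """Label blocks HS (identity > 95%) or MS (90-95%), and summarize.

    With ``non_par_len`` given, reports the fraction of the non-PAR region
    covered by labeled blocks; coverage of HS blocks above 95% is flagged as
    the architecture in which a few large high-identity blocks protect
    nearly the whole male-specific region.
    """
    out: list[SelfSimBlock] = []
    for b in blocks:
        if not isinstance(b, SelfSimBlock):
            b = SelfSimBlock(*b)
        if not 0.0 <= b.identity <= 1.0:
            raise RepeatError("identity must be in [0, 1]")
        if b.identity > hs_threshold:
            b.label = "HS"
        elif ms_low <= b.identity <= hs_threshold:
            b.label = "MS"
        else:
            b.label = ""
        out.append(b)
    summary = {"blocks": out,
               "n_hs": sum(b.label == "HS" for b in out),
               "n_ms": sum(b.label == "MS" for b in out)}
    if non_par_len:
        merged = _merge_intervals([(b.start, b.end) for b in out if b.label])
        cov = sum(e - s + 1 for s, e in merged)
        hs_merged = _merge_intervals([(b.start, b.end) for b in out if b.label == "HS"])
        hs_cov = sum(e - s + 1 for s, e in hs_merged)
        summary["labeled_coverage"] = cov / non_par_len
        summary["hs_coverage"] = hs_cov / non_par_len
        summary["architecture"] = ("saturated-HS" if hs_cov / non_par_len > 0.95
                                   else "mixed")
    return summary
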