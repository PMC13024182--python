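"""Ampliconic gene census: ASC / TSC / hTSC stratification and dosage ratios.

Ampliconic Y-linked families (TSPY, HSFY, ZNF280BY, PRAMEY, RBMY, ...) exist
as tens to hundreds of near-identical copies. The census stratifies copies
by evidence tier:

* **ASC** (Annotation-Supported Copy): an annotated copy whose genomic CDS
  is a complete ORF — start codon, terminal stop, in-frame length, no
  internal stop. Pseudogenized copies fail this test.
* **TSC** (Transcript-Supported Copy): an ASC to which short-read
  transcriptome alignments map. Short reads multi-map among near-identical
  copies, so the TSC count is an inflated upper bound on active copies.
* **hTSC** (high-confidence TSC): a TSC additionally supported by long
  full-length transcript alignments, which place uniquely and give the
  accurate active-copy count.

Containment hTSC <= TSC <= ASC holds by construction. Cross-species dosage
is summarized as the ratio of one species' hTSC count to the other's TSC
count, rounded half-up to two decimals, plus an ASC-count amplification
tier label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._util import round_half_up

TIER_LABELS = ("1–10", "10–50", "50–100", "100–200", "other")


class CensusError(ValueError):
    pass


@dataclass
class GeneModel:
    """One annotated gene copy. Coordinates are 1-based inclusive; exons and
    CDS parts are (start, end) pairs, sorted and non-overlapping."""

    copy_id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    source: str = "liftover"  # liftover | denovo
    # lift-over metadata (None for de novo models)
    coverage: float | None = None
    identity: float | None = None
    structure_preserved: bool | None = None
    n_best_mappings: int | None = None

    def __post_init__(self):
        for parts in (self.exons, self.cds):
            parts.sort()
            for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.copy_id}: overlapping parts")


@dataclass
class AmpliconCopy:
    model: GeneModel
    asc: bool = False
    tsc: bool = False
    htsc: bool = False
    short_read_count: int = 0
    long_read_count: int = 0
    domain_present: bool | None = None


# ---------------------------------------------------------------------------
# annotation filtering and merging


def filter_liftover(candidates: list[GeneModel], min_coverage: float = 0.5,
                    ) -> tuple[list[GeneModel], list[tuple[GeneModel, str]]]:
    """Accept lifted-over models meeting all three transfer conditions:
    coverage >= ``min_coverage``, preserved exon-intron structure, and a
    unique best mapping (one-to-one orthology). Rejects carry a reason."""
    accepted, rejected = [], []
    for m in candidates:
        if m.coverage is None or m.structure_preserved is None or m.n_best_mappings is None:
            raise CensusError(f"{m.copy_id}: missing lift-over metadata")
        if m.coverage < min_coverage:
            rejected.append((m, f"coverage {m.coverage:.2f} < {min_coverage}"))
        elif not m.structure_preserved:
            rejected.append((m, "gene structure not preserved"))
        elif m.n_best_mappings != 1:
            rejected.append((m, f"{m.n_best_mappings} equal-best mappings (non-unique)"))
        else:
            accepted.append(m)
    return accepted, rejected


def merge_annotations(primary: list[GeneModel], denovo: list[GeneModel],
                      ) -> list[GeneModel]:
    """Primary (lift-over) models plus the de novo models that have zero
    same-strand exonic overlap with any primary model. Deterministic order:
    primary first, then surviving de novo, each by coordinate."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in primary:
        t = trees.setdefault((m.chrom, m.strand), IntervalTree())
        for s, e in (m.exons or [(m.start, m.end)]):
            t.addi(s, e + 1)  # half-open
    kept = []
    for m in denovo:
        t = trees.get((m.chrom, m.strand))
        exons = m.exons or [(m.start, m.end)]
        if t is None or not any(t.overlap(s, e + 1) for s, e in exons):
            kept.append(m)
    key = lambda m: (m.chrom, m.start, m.end, m.copy_id)
    return sorted(primary, key=key) + sorted(kept, key=key)


# ---------------------------------------------------------------------------
# tier calls


def extract_cds(model: GeneModel, genome: dict[str, str] | str) -> str:
    """Spliced, strand-corrected CDS nucleotide sequence."""
    seq = genome[model.chrom] if isinstance(genome, dict) else str(genome)
    parts = model.cds or model.exons or [(model.start, model.end)]
    if parts[-1][1] > len(seq) or parts[0][0] < 1:
        raise CensusError(f"{model.copy_id}: interval outside genome ({model.chrom})")
    s = "".join(seq[a - 1:b] for a, b in parts).upper()
    if model.strand == "-":
        s = str(Seq(s).reverse_complement())
    return s


def is_complete_orf(cds: str) -> bool:
    if len(cds) < 6 or len(cds) % 3:
        return False
    if not cds.startswith("ATG") or cds[-3:] not in ("TAA", "TAG", "TGA"):
        return False
    prot = Seq(cds).translate()
    return "*" not in prot[:-1]


def call_asc(models: list[GeneModel], genome) -> list[AmpliconCopy]:
    """Flag each copy as ASC iff its genomic CDS is a complete ORF."""
    return [AmpliconCopy(model=m, asc=is_complete_orf(extract_cds(m, genome)))
            for m in models]


def count_support(copies: list[AmpliconCopy], alignments, mode: str,
                  min_mapq: int = 20, min_overlap_frac: float = 0.5,
                  seed: int = 0) -> list[AmpliconCopy]:
    """Accumulate per-copy transcriptome read counts.

    ``alignments`` is a SAM path/file (parsed with pysam) or an iterable of
    objects with ``read_name, chrom, pos, mapq, is_primary`` plus a query
    length (``qlen``/CIGAR). Short mode counts each read once, at its primary
    placement; when an aligner has not designated a primary among equal-best
    placements one is chosen seeded-random, mirroring short-read aligner
    behavior. Long mode counts primary placements with MAPQ >=
    ``min_mapq``. A read supports the copy whose span contains at least
    ``min_overlap_frac`` of it.
    """
    if mode not in ("short", "long"):
        raise CensusError(f"unknown mode: {mode!r}")
    import numpy as np

    rng = np.random.default_rng(seed)
    recs = _iter_alignments(alignments)

    trees: dict[str, IntervalTree] = {}
    chroms = set()
    for i, c in enumerate(copies):
        m = c.model
        chroms.add(m.chrom)
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end + 1, i)

    by_read: dict[str, list] = {}
    for r in recs:
        if r["chrom"] not in chroms:
            raise CensusError(f"alignment {r['name']!r}: unknown chrom {r['chrom']!r}")
        by_read.setdefault(r["name"], []).append(r)

    for name, placements in sorted(by_read.items()):
        primaries = [r for r in placements if r["is_primary"]]
        if mode == "short":
            if primaries:
                chosen = primaries[0]
            else:
                chosen = placements[int(rng.integers(len(placements)))]
            hits = [chosen]
        else:
            hits = [r for r in primaries if r["mapq"] >= min_mapq]
        for r in hits:
            span = (r["pos"], r["pos"] + r["length"])  # half-open
            for iv in trees.get(r["chrom"], IntervalTree()).overlap(*span):
                ov = min(iv.end - 1, span[1] - 1) - max(iv.begin, span[0]) + 1
                if ov >= min_overlap_frac * r["length"]:
                    c = copies[iv.data]
                    if mode == "short":
                        c.short_read_count += 1
                    else:
                        c.long_read_count += 1
    return copies


def _iter_alignments(alignments):
    import os

    if isinstance(alignments, (str, os.PathLike)):
        import pysam

        with pysam.AlignmentFile(str(alignments), check_sq=False) as sam:
            out = []
            for seg in sam:
                if seg.is_unmapped:
                    continue
                out.append({"name": seg.query_name,
                            "chrom": seg.reference_name,
                            "pos": seg.reference_start + 1,
                            "mapq": seg.mapping_quality,
                            "is_primary": not (seg.is_secondary or seg.is_supplementary),
                            "length": seg.query_length or seg.infer_query_length() or
                            (seg.reference_end - seg.reference_start)})
            return out
    out = []
    for a in alignments:
        if isinstance(a, dict):
            out.append(a)
        else:  # e.g. simulate.SimAlignment
            out.append({"name": a.read_name, "chrom": a.chrom, "pos": a.pos,
                        "mapq": a.mapq, "is_primary": a.is_primary,
                        "length": getattr(a, "length", 0)})
    return out


def stratify(copies: list[AmpliconCopy], min_short: int = 1, min_long: int = 1,
             ) -> list[AmpliconCopy]:
    """TSC = ASC with >= ``min_short`` short reads; hTSC = TSC with >=
    ``min_long`` long reads. Enforces hTSC => TSC => ASC."""
    for c in copies:
        c.tsc = bool(c.asc and c.short_read_count >= min_short)
        c.htsc = bool(c.tsc and c.long_read_count >= min_long)
    return copies


def domain_check(copies: list[AmpliconCopy], genome, motif: str | None = None,
                 pssm=None, min_score: float = 1.0) -> list[AmpliconCopy]:
    """Verify a conserved peptide domain in each copy's translated CDS.

    With a ``motif`` string the check is presence of the exact peptide; with
    a ``pssm`` (mapping position -> {aa: score}) the best window score must
    reach ``min_score``.
    """
    if motif is None and pssm is None:
        raise CensusError("domain_check needs a motif or a PSSM")
    for c in copies:
        cds = extract_cds(c.model, genome)
        if c.asc and (len(cds) % 3 or not cds):
            raise CensusError(f"{c.model.copy_id}: asc=True but CDS untranslatable")
        prot = str(Seq(cds[:len(cds) - len(cds) % 3]).translate()).rstrip("*")
        if motif is not None:
            c.domain_present = motif in prot
        else:
            w = len(pssm)
            best = max((sum(pssm[i].get(prot[j + i], 0.0) for i in range(w))
                        for j in range(max(0, len(prot) - w + 1))), default=0.0)
            c.domain_present = best >= min_score
    return copies


# ---------------------------------------------------------------------------
# summaries


def copy_ratio(numerator_count: int, denominator_count: int) -> float | None:
    """Cross-species dosage ratio, half-up to 2 decimals. A 0/0 family is
    'inactive' and reports 0.00; a nonzero numerator over a zero denominator
    is undefined (None)."""
    if denominator_count == 0:
        return 0.0 if numerator_count == 0 else None
    return round_half_up((numerator_count, denominator_count), 2)


def tier_classify(asc_count: int) -> str:
    """Amplification tier from the ASC count. Boundaries are half-open
    [lo, hi) except the first tier, which is the closed range [1, 10]."""
    if asc_count < 0:
        raise ValueError("count must be >= 0")
    if 1 <= asc_count <= 10:
        return TIER_LABELS[0]
    if 10 < asc_count < 50:
        return TIER_LABELS[1]
    if 50 <= asc_count < 100:
        return TIER_LABELS[2]
    if 100 <= asc_count < 200:
        return TIER_LABELS[3]
    return TIER_LABELS[4]


def models_from_gff3(text: str, family_attr: str = "family") -> list[GeneModel]:
    """Read gene models from GFF3 (gffutils in-memory DB).

    The family name is taken from the ``family`` attribute when present,
    else from the gene's Name/ID with a trailing copy suffix stripped.
    """
    import gffutils

    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        copy_id = gene.attributes.get("ID", [gene.id])[0]
        family = gene.attributes.get(family_attr, [copy_id.rsplit("_", 1)[0]])[0]
        source = gene.attributes.get("source_set", [gene.source])[0]
        models.append(GeneModel(copy_id=copy_id, family=family, chrom=gene.seqid,
                                start=gene.start, end=gene.end, strand=gene.strand,
                                exons=sorted(exons), cds=sorted(cds),
                                source=source if source in ("liftover", "denovo") else "liftover"))
    return models


def models_to_gff3(models: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = f"ID={m.copy_id};family={m.family};source_set={m.source}"
        lines.append(f"{m.chrom}\t{m.source}\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}")
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(f"{m.chrom}\t{m.source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.copy_id}.exon{i};Parent={m.copy_id}")
        for i, (s, e) in enumerate(m.cds, 1):
            lines.append(f"{m.chrom}\t{m.source}\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                         f"ID={m.copy_id}.cds{i};Parent={m.copy_id}")
    return "\n".join(lines) + "\n"


def models_from_truth(truth, chrom: str = "Y", source: str = "liftover") -> list[GeneModel]:
    """Gene models for every planted copy in a simulation Truth object."""
    return [GeneModel(copy_id=rec.copy_id, family=rec.family, chrom=chrom,
                      start=rec.start, end=rec.end, strand=rec.strand,
                      exons=[(rec.start, rec.end)],
                      cds=[(rec.cds_start, rec.cds_end)], source=source)
            for rec in truth.copy_coords.values()]


def census_table(copies: list[AmpliconCopy], species: str = "yak"):
    """Per-family ASC/TSC/hTSC counts as a DataFrame."""
    import pandas as pd

    rows: dict[str, dict] = {}
    for c in copies:
        fam = rows.setdefault(c.model.family,
                              {"family": c.model.family, "species": species,
                               "ASC": 0, "TSC": 0, "hTSC": 0})
        fam["ASC"] += c.asc
        fam["TSC"] += c.tsc
        fam["hTSC"] += c.htsc
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["family"]))
    if not df.empty:
        df["tier"] = df["ASC"].map(tier_classify)
    return df
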