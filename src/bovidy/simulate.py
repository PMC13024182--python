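"""Synthetic sex-chromosome, read, graph, and depth-track generator.

Everything downstream in this package (consensus voting, boundary calling,
the ampliconic census) is exercised against data produced here, where the
ground truth — the pseudoautosomal boundary, the coordinates and expression
status of every planted gene copy, the majority path through the graph — is
known by construction.

The generator emulates the statistical structure of a bovid Y chromosome:

* a pseudoautosomal region (PAR) shared base-for-base between X and Y,
  followed by divergent male-specific sequence (MSY);
* a telomeric tandem-motif array (CCCTAA by default) at position 1;
* ampliconic gene families planted as arrays of near-identical copies, a
  configurable fraction pseudogenized (disrupted ORF) and a configurable
  fraction transcriptionally silent;
* short transcriptome reads that multi-map among near-identical copies and
  long reads that span whole copies and place uniquely;
* a backbone-plus-bubbles pangenome graph with per-sample walks;
* male/female sequencing-depth tracks that diverge at the PAR boundary.

Coordinates in emitted truth are 1-based inclusive; internal arithmetic is
0-based half-open. The read error model is substitution-only, which keeps
the brute-force read-placement oracle exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# one representative codon per amino acid; none can mutate silently into a stop
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOPS = {"TAA", "TAG", "TGA"}
_AA = "".join(sorted(_CODON))


class SizingError(ValueError):
    """Chromosome too small to host telomere + PAR + planted families."""


@dataclass
class FamilySpec:
    """One ampliconic family to plant as a multi-copy array.

    ``expressed_copies`` may be left None, in which case it is derived from
    ``SimConfig.silent_fraction`` over the intact (non-pseudogenized) copies.
    Expressed copies are always drawn from intact copies.
    """

    name: str
    n_copies: int
    unit_len: int = 600
    expressed_copies: int | None = None
    domain_motif: str = "WNDPHMKQ"

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValueError(f"{self.name}: n_copies must be >= 1")
        if self.unit_len < 120:
            raise ValueError(f"{self.name}: unit_len must be >= 120 bp")
        if self.expressed_copies is not None and self.expressed_copies > self.n_copies:
            raise ValueError(f"{self.name}: expressed_copies > n_copies")


def default_families() -> list[FamilySpec]:
    """A four-tier family panel at roughly 1/10 the copy counts observed on
    real bovid Y chromosomes (a 100-200-copy tier, a 50-100 tier, a 10-50
    tier, and a 1-10 tier)."""
    return [
        FamilySpec("TSPY1like", 20, 600),
        FamilySpec("ZNFlike", 10, 600),
        FamilySpec("HSFYlike", 7, 600),
        FamilySpec("RBMYlike", 3, 600),
    ]


@dataclass
class SimConfig:
    """Study-condition parameters, defaulting to a 1/100-scale chromosome
    (42.4 Mb -> 424 kb; 6.84 Mb PAR -> 68.4 kb; 18.9 kb telomere -> 189 bp)."""

    seed: int = 0
    chrom_len: int = 424_173
    par_len: int = 68_400
    telomere_motif: str = "CCCTAA"
    telomere_len: int = 189
    families: list[FamilySpec] = field(default_factory=default_families)
    short_read_len: int = 100
    long_read_len_mean: int = 5_000
    read_depth: float = 10.0
    copy_divergence: float = 0.01
    silent_fraction: float = 0.5
    pseudogene_fraction: float = 0.25
    read_error_rate: float = 0.0

    def to_yaml(self) -> str:
        import yaml

        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        import yaml

        d = yaml.safe_load(text)
        d["families"] = [FamilySpec(**f) for f in d.get("families", [])]
        return cls(**d)

    def validate(self) -> None:
        if not 0 <= self.par_len < self.chrom_len:
            raise ValueError("require 0 <= par_len < chrom_len")
        for name in ("silent_fraction", "pseudogene_fraction", "copy_divergence",
                     "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.telomere_len >= self.chrom_len:
            raise ValueError("telomere_len must be < chrom_len")
        if len(self.telomere_motif) < 2:
            raise ValueError("telomere motif must be >= 2 bp")


@dataclass
class CopyRecord:
    """One planted gene copy (1-based inclusive coordinates on Y)."""

    copy_id: str
    family: str
    start: int
    end: int
    cds_start: int
    cds_end: int
    strand: str = "+"


@dataclass
class Truth:
    """Ground-truth sidecar for one simulated chromosome pair."""

    par_boundary: int
    chrom_len: int
    copy_coords: dict[str, CopyRecord] = field(default_factory=dict)
    expressed_set: set[str] = field(default_factory=set)
    pseudogene_set: set[str] = field(default_factory=set)
    graph_truth_path: list[str] | None = None

    def validate(self) -> None:
        for cid in self.expressed_set:
            if cid not in self.copy_coords:
                raise ValueError(f"expressed copy {cid} missing from copy_coords")
        for rec in self.copy_coords.values():
            if not 1 <= rec.start <= rec.end <= self.chrom_len:
                raise ValueError(f"{rec.copy_id}: interval outside [1, chrom_len]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["copy_coords"] = {k: dataclasses.asdict(v) if not isinstance(v, dict) else v
                            for k, v in self.copy_coords.items()}
        d["expressed_set"] = sorted(self.expressed_set)
        d["pseudogene_set"] = sorted(self.pseudogene_set)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Truth":
        d = json.loads(text)
        d["copy_coords"] = {k: CopyRecord(**v) for k, v in d["copy_coords"].items()}
        d["expressed_set"] = set(d["expressed_set"])
        d["pseudogene_set"] = set(d["pseudogene_set"])
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence construction


def _rand_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.uint8)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def _encode_peptide(pep: str) -> str:
    return "".join(_CODON[a] for a in pep)


def _make_master_unit(spec: FamilySpec, rng: np.random.Generator) -> tuple[str, int, int]:
    """Build the ancestral unit: 5'UTR + ORF (ATG .. TAA) + 3'UTR.

    Returns (unit sequence, cds_start, cds_end) with 0-based half-open CDS.
    """
    utr5 = 15
    n_codons = (spec.unit_len - 2 * utr5) // 3
    n_codons -= (spec.unit_len - 2 * utr5 - n_codons * 3 == 0)  # keep >=1 bp UTR3
    n_aa = n_codons - 2  # minus start and stop
    motif = spec.domain_motif
    if n_aa < len(motif) + 4:
        raise ValueError(f"{spec.name}: unit too short for domain motif")
    flank = n_aa - len(motif)
    left = flank // 2
    pep = ("".join(rng.choice(list(_AA), left)) + motif
           + "".join(rng.choice(list(_AA), flank - left)))
    cds = "ATG" + _encode_peptide(pep) + "TAA"
    utr3 = spec.unit_len - utr5 - len(cds)
    unit = (_codes_to_str(_rand_dna(rng, utr5)) + cds
            + _codes_to_str(_rand_dna(rng, utr3)))
    return unit, utr5, utr5 + len(cds)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = _str_to_codes(seq).copy()
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, n_mut)) % 4
    return _codes_to_str(codes)


def _repair_orf(unit: str, master: str, cds_s: int, cds_e: int, motif_span: tuple[int, int]) -> str:
    """Restore an intact ORF (and the domain-coding stretch) after mutation."""
    u = list(unit)
    u[cds_s:cds_s + 3] = "ATG"
    u[cds_e - 3:cds_e] = "TAA"
    u[motif_span[0]:motif_span[1]] = master[motif_span[0]:motif_span[1]]
    for i in range(cds_s + 3, cds_e - 3, 3):
        if "".join(u[i:i + 3]) in _STOPS:
            u[i] = "C"
    return "".join(u)


def _break_orf(unit: str, cds_s: int, cds_e: int) -> str:
    """Pseudogenize: plant an in-frame premature stop mid-CDS."""
    n_codons = (cds_e - cds_s) // 3
    i = cds_s + 3 * (n_codons // 2)
    return unit[:i] + "TAA" + unit[i + 3:]


def simulate_sex_chromosomes(config: SimConfig) -> tuple[SeqRecord, SeqRecord, Truth]:
    """Generate an (X, Y) pair plus ground truth.

    The first ``par_len`` bases of X and Y are identical (the PAR, telomere
    array included); sequence beyond is independently random. Ampliconic
    family copies are planted in the MSY with the configured inter-copy
    divergence; intact copies keep a clean ORF carrying the family's domain
    motif, pseudogenized copies carry an in-frame premature stop.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    y = _rand_dna(rng, config.chrom_len)
    x = _rand_dna(rng, config.chrom_len)

    telo = (config.telomere_motif
            * (config.telomere_len // len(config.telomere_motif) + 1))[:config.telomere_len]
    telo_codes = _str_to_codes(telo)
    y[:config.telomere_len] = telo_codes
    x[:config.telomere_len] = telo_codes
    # break the motif phase right after the array so it is maximal by construction
    t = config.telomere_len
    next_code = _str_to_codes(config.telomere_motif[t % len(config.telomere_motif)])[0]
    for chrom in (x, y):
        if chrom[t] == next_code:
            chrom[t] = (next_code + 1) % 4
    if config.par_len:
        x[:config.par_len] = y[:config.par_len]

    truth = Truth(par_boundary=config.par_len, chrom_len=config.chrom_len)
    margin = 1_000
    cursor = config.par_len + margin
    for spec in config.families:
        master, cds_s, cds_e = _make_master_unit(spec, rng)
        # motif-coding span inside the CDS, 0-based on the unit
        pep = str(Seq(master[cds_s:cds_e]).translate())
        rel = pep.find(spec.domain_motif)
        motif_span = (cds_s + 3 * rel, cds_s + 3 * (rel + len(spec.domain_motif)))

        n_pseudo = int(round(config.pseudogene_fraction * spec.n_copies))
        n_pseudo = min(n_pseudo, spec.n_copies - 1)  # keep >=1 intact copy
        ids = [f"{spec.name}_{i + 1}" for i in range(spec.n_copies)]
        pseudo_ids = set(map(str, rng.choice(ids, size=n_pseudo, replace=False)))
        intact_ids = [i for i in ids if i not in pseudo_ids]
        if spec.expressed_copies is None:
            n_expr = int(round((1.0 - config.silent_fraction) * len(intact_ids)))
        else:
            n_expr = min(spec.expressed_copies, len(intact_ids))
        expressed = (set(map(str, rng.choice(intact_ids, size=n_expr, replace=False)))
                     if n_expr else set())

        for cid in ids:
            unit = _mutate(master, config.copy_divergence, rng)
            if cid in pseudo_ids:
                unit = _break_orf(unit, cds_s, cds_e)
            else:
                unit = _repair_orf(unit, master, cds_s, cds_e, motif_span)
            start0 = cursor
            end0 = start0 + spec.unit_len
            if end0 > config.chrom_len - margin:
                raise SizingError(
                    f"chrom_len={config.chrom_len} too small for PAR + telomere "
                    f"+ planted families (ran out at {spec.name})")
            y[start0:end0] = _str_to_codes(unit)
            truth.copy_coords[cid] = CopyRecord(
                copy_id=cid, family=spec.name,
                start=start0 + 1, end=end0,
                cds_start=start0 + cds_s + 1, cds_end=start0 + cds_e)
            cursor = end0 + int(rng.integers(200, 1_000))
        truth.pseudogene_set |= pseudo_ids
        truth.expressed_set |= expressed

    truth.validate()
    x_rec = SeqRecord(Seq(_codes_to_str(x)), id="X", description="simulated X")
    y_rec = SeqRecord(Seq(_codes_to_str(y)), id="Y", description="simulated Y")
    return x_rec, y_rec, truth


# ---------------------------------------------------------------------------
# reads and their surrogate alignments


@dataclass
class SimRead:
    name: str
    seq: str
    source_copy: str
    source_start: int  # 1-based on Y


@dataclass
class SimAlignment:
    read_name: str
    chrom: str
    pos: int  # 1-based leftmost
    mapq: int
    is_primary: bool
    copy_id: str
    nm: int
    length: int = 0  # aligned read length


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def simulate_reads(y_seq, truth: Truth, mode: str, config: SimConfig,
                   ) -> tuple[list[SimRead], list[SimAlignment]]:
    """Emit transcriptome reads from expressed copies plus surrogate alignments.

    Short mode fragments each expressed transcript into reads of
    ``short_read_len``; every read is scored against the homologous offset of
    every same-family copy (exhaustive Hamming placement, exact because the
    error model is substitution-only). All equally-best placements are
    reported; the primary is a seeded random choice among them, mirroring a
    short-read aligner's tie-breaking. Long mode emits ``round(read_depth)``
    full-length transcript reads per expressed copy; placement is unique
    (MAPQ 60) whenever one copy scores strictly best.
    """
    if mode not in ("short", "long"):
        raise ValueError(f"unknown read mode: {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7 if mode == "short" else 11]))
    y = _str_to_codes(str(y_seq.seq) if isinstance(y_seq, SeqRecord) else str(y_seq))

    by_family: dict[str, list[CopyRecord]] = {}
    for rec in truth.copy_coords.values():
        by_family.setdefault(rec.family, []).append(rec)
    for copies in by_family.values():
        copies.sort(key=lambda r: r.start)

    reads: list[SimRead] = []
    alns: list[SimAlignment] = []
    serial = 0
    for family, copies in sorted(by_family.items()):
        expressed = [c for c in copies if c.copy_id in truth.expressed_set]
        for src in expressed:
            cds0, cds1 = src.cds_start - 1, src.cds_end  # 0-based half-open
            tlen = cds1 - cds0
            if mode == "short":
                rlen = min(config.short_read_len, tlen)
                n_reads = max(1, int(np.ceil(config.read_depth * tlen / rlen)))
                offsets = rng.integers(0, tlen - rlen + 1, n_reads)
            else:
                rlen = tlen  # full-length transcript
                n_reads = max(1, int(round(config.read_depth)))
                offsets = np.zeros(n_reads, dtype=int)
            for off in offsets:
                serial += 1
                raw = y[cds0 + off:cds0 + off + rlen]
                seq = _str_to_codes(_mutate(_codes_to_str(raw), config.read_error_rate, rng))
                name = f"{mode}_{serial}_{src.copy_id}"
                reads.append(SimRead(name, _codes_to_str(seq), src.copy_id, cds0 + off + 1))
                # exhaustive placement against every same-family copy
                scores = []
                for cand in copies:
                    p0 = cand.cds_start - 1 + off
                    scores.append((_hamming(seq, y[p0:p0 + rlen]), cand))
                best = min(s for s, _ in scores)
                ties = [c for s, c in scores if s == best]
                primary = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
                mapq = 60 if len(ties) == 1 else 0
                for cand in ties:
                    alns.append(SimAlignment(
                        read_name=name, chrom="Y",
                        pos=cand.cds_start + int(off),
                        mapq=mapq, is_primary=cand is primary,
                        copy_id=cand.copy_id, nm=best, length=rlen))
    return reads, alns


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_sam(alignments: list[SimAlignment], reads: list[SimRead],
              chrom_len: int, path, chrom: str = "Y") -> None:
    """Write surrogate alignments as plain-text SAM (via pysam)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    })
    seq_of = {r.name: r.seq for r in reads}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_name
            seg.flag = 0 if a.is_primary else 0x100
            seg.reference_id = 0
            seg.reference_start = a.pos - 1
            seg.mapping_quality = a.mapq
            seq = seq_of[a.read_name]
            seg.cigarstring = f"{len(seq)}M"
            if a.is_primary:
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.set_tag("NM", a.nm)
            out.write(seg)


# ---------------------------------------------------------------------------
# pangenome graph


def simulate_pangraph(backbone_len_segments: int, n_samples: int,
                      bubble_spec=None, seed: int = 0,
                      seg_len: tuple[int, int] = (30, 80)):
    """Build a linear backbone with inserted bubbles and per-sample walks.

    ``bubble_spec`` is either an int (that many randomly placed bubbles, each
    with 2-3 branches) or an explicit list of ``(backbone_index, n_branches)``
    pairs, where the bubble replaces backbone segment ``backbone_index`` with
    ``n_branches`` alternatives (the backbone's own segment counts as branch
    0). Bubble anchor indices must be separated by >= 2 segments so sample
    walks stay well formed.

    Returns ``(gfa_text, walks, truth_path)`` where walks is a list of
    ``(sample_name, [segment, ...])`` and truth_path is the branch-majority
    walk (ties resolved toward the backbone).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if backbone_len_segments < 3:
        raise ValueError("need >= 3 backbone segments")
    rng = np.random.default_rng(seed)

    if bubble_spec is None:
        bubble_spec = 0
    if isinstance(bubble_spec, int):
        eligible = list(range(1, backbone_len_segments - 1))
        chosen: list[int] = []
        rng.shuffle(eligible)
        for m in eligible:
            if len(chosen) >= bubble_spec:
                break
            if all(abs(m - c) >= 2 for c in chosen):
                chosen.append(m)
        bubble_spec = [(m, int(rng.integers(2, 4))) for m in sorted(chosen)]
    else:
        bubble_spec = sorted(bubble_spec)
        for (m, k) in bubble_spec:
            if not 1 <= m <= backbone_len_segments - 2:
                raise ValueError(f"bubble index {m} not interior to the backbone")
            if k < 2:
                raise ValueError("bubble must have >= 2 branches")
        for (m1, _), (m2, _) in zip(bubble_spec, bubble_spec[1:]):
            if m2 - m1 < 2:
                raise ValueError("bubble anchor indices must be >= 2 apart")

    def rand_seq():
        return _codes_to_str(_rand_dna(rng, int(rng.integers(*seg_len))))

    backbone = [f"b{i}" for i in range(backbone_len_segments)]
    segments = {name: rand_seq() for name in backbone}
    links = [(backbone[i], "+", backbone[i + 1], "+")
             for i in range(backbone_len_segments - 1)]

    bubbles = []  # (index m, [branch segment names]); branch 0 = backbone's own
    for bi, (m, k) in enumerate(bubble_spec):
        branch_segs = [backbone[m]]
        for j in range(1, k):
            alt = f"u{bi}_{j}"
            segments[alt] = rand_seq()
            links.append((backbone[m - 1], "+", alt, "+"))
            links.append((alt, "+", backbone[m + 1], "+"))
            branch_segs.append(alt)
        bubbles.append((m, branch_segs))

    walks = []
    support = [np.zeros(len(b[1]), dtype=int) for b in bubbles]
    for s in range(n_samples):
        choice = {m: int(rng.integers(len(branch_segs)))
                  for (m, branch_segs) in bubbles}
        for bi, (m, _) in enumerate(bubbles):
            support[bi][choice[m]] += 1
        walk = []
        for i, seg in enumerate(backbone):
            picked = seg
            for (m, branch_segs) in bubbles:
                if i == m:
                    picked = branch_segs[choice[m]]
            walk.append(picked)
        walks.append((f"sample{s + 1}", walk))

    truth_path = []
    for i, seg in enumerate(backbone):
        picked = seg
        for bi, (m, branch_segs) in enumerate(bubbles):
            if i == m:
                counts = support[bi]
                top = counts.max()
                picked = branch_segs[0] if counts[0] == top else branch_segs[int(counts.argmax())]
        truth_path.append(picked)

    lines = ["H\tVN:Z:1.0"]
    for name in sorted(segments):
        lines.append(f"S\t{name}\t{segments[name]}")
    for a, ao, b, bo in links:
        lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M")
    lines.append("P\tbackbone\t" + ",".join(f"{s}+" for s in backbone) + "\t*")
    gfa_text = "\n".join(lines) + "\n"
    return gfa_text, walks, truth_path


def walks_to_tsv(walks) -> str:
    """Serialize sample walks as the 2-column sample / oriented-path TSV."""
    return "".join(f"{name}\t{''.join('>' + s for s in path)}\n" for name, path in walks)


# ---------------------------------------------------------------------------
# depth tracks


def simulate_depth_tracks(truth: Truth, sex: str, noise_sd: float, seed: int = 0,
                          mean_depth: float = 30.0) -> np.ndarray:
    """Per-base depth for one sex: females drop to ~0 beyond the PAR boundary,
    males stay uniform. Gaussian noise with the given sd, clipped at 0.
    Index i of the returned array is base i+1."""
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex: {sex!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    n = truth.chrom_len
    depth = np.full(n, mean_depth, dtype=float)
    if sex == "female":
        depth[truth.par_boundary:] = 0.0
    if noise_sd > 0:
        depth += rng.normal(0.0, noise_sd, n)
    return np.clip(depth, 0.0, None)


def write_depth_tsv(depth: np.ndarray, path, chrom: str = "Y") -> None:
    """3-column TSV: chrom, 1-based position, depth."""
    with open(path, "w") as fh:
        for i, d in enumerate(depth, 1):
            fh.write(f"{chrom}\t{i}\t{d:.3f}\n")
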