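"""Pseudoautosomal boundary fine-mapping, telomere finding, alignment shifts.

The pseudoautosomal boundary (PAB) is the base at which X-Y homology ends.
Two independent locators are provided:

* ``windowed_identity`` + ``refine_breakpoint``: a coarse windowed identity
  scan between the X-homologous and Y sequence followed by base-level global
  alignment inside the candidate interval, calling the boundary at the end
  of the last long perfect-match run before identity collapses;
* ``coverage_boundary``: the termination point of female sequencing depth on
  the Y, with the male track as a control against assembly truncation.

On data where both apply the two calls are expected to agree to within a few
hundred bases. ``find_telomere`` locates terminal tandem-motif arrays and
``alignment_shift_profile`` summarizes reference-vs-query start offsets of
PAF alignments into the collinearity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._util import revcomp


class BoundaryError(ValueError):
    pass


class BoundaryRejected(BoundaryError):
    """Raised when the control track invalidates a coverage boundary call."""


@dataclass
class IdentityWindow:
    window_start: int  # 1-based
    window_len: int
    identity: float


@dataclass
class IdentityProfile:
    windows: list[IdentityWindow]
    refined_base: int | None = None


@dataclass
class BoundaryCall:
    method: str  # "identity" | "coverage"
    coordinate: int  # 1-based bp
    interval: tuple[int, int]
    support: dict = field(default_factory=dict)


@dataclass
class TelomereCall:
    motif: str
    start: int  # 1-based
    end: int
    length: int
    divergence: float


# ---------------------------------------------------------------------------


def windowed_identity(seq_a, seq_b, window: int = 5_000) -> IdentityProfile:
    """Tile the positionally comparable span of two sequences into windows
    and report per-window base identity (matches / window length)."""
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    a = np.frombuffer(str(seq_a).upper().encode(), np.uint8)
    b = np.frombuffer(str(seq_b).upper().encode(), np.uint8)
    n = min(a.size, b.size)
    if n == 0:
        raise BoundaryError("empty overlap between sequences")
    eq = a[:n] == b[:n]
    windows = []
    for s in range(0, n, window):
        w = eq[s:s + window]
        windows.append(IdentityWindow(window_start=s + 1, window_len=w.size,
                                      identity=float(w.mean())))
    return IdentityProfile(windows=windows)


def _aligner(match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _alignment_columns(aln) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (a position or -1, b position or -1, match flag)."""
    a_str, b_str = str(aln[0]), str(aln[1])
    apos, bpos, match = [], [], []
    ia = ib = 0
    for ca, cb in zip(a_str, b_str):
        apos.append(ia if ca != "-" else -1)
        bpos.append(ib if cb != "-" else -1)
        match.append(ca == cb and ca != "-")
        ia += ca != "-"
        ib += cb != "-"
    return np.array(apos), np.array(bpos), np.array(match, dtype=bool)


def refine_breakpoint(seq_a, seq_b, coarse_interval: tuple[int, int],
                      min_match_run: int = 50, probe_len: int = 500,
                      divergence_threshold: float = 0.8,
                      scores: tuple = (1.0, -2.0, -5.0, -1.0)) -> BoundaryCall:
    """Base-level boundary refinement inside a coarse interval.

    Both sequences are globally aligned (affine gaps) over the 1-based
    inclusive ``coarse_interval``; the boundary is the ``seq_a`` position of
    the last column ending a run of >= ``min_match_run`` consecutive matches
    whose following ``probe_len`` alignment columns fall below
    ``divergence_threshold`` identity. The first post-boundary indel, if
    any, is reported in the call's support.
    """
    lo, hi = coarse_interval
    a = str(seq_a).upper()[lo - 1:hi]
    b = str(seq_b).upper()[lo - 1:hi]
    if not a or not b:
        raise BoundaryError("coarse interval empty on one sequence")
    aln = _aligner(*scores).align(a, b)[0]
    apos, bpos, match = _alignment_columns(aln)

    # run length of consecutive matches ending at each column
    run = np.zeros(match.size, dtype=int)
    for i, m in enumerate(match):
        run[i] = run[i - 1] + 1 if m and i else int(m)
    csum = np.concatenate([[0], np.cumsum(match)])

    boundary_col = None
    for i in range(match.size):
        if run[i] < min_match_run:
            continue
        j = min(i + 1 + probe_len, match.size)
        if j - (i + 1) < probe_len // 2:  # not enough downstream sequence to probe
            continue
        probe_ident = (csum[j] - csum[i + 1]) / (j - i - 1)
        if probe_ident < divergence_threshold:
            boundary_col = i
    if boundary_col is None:
        raise BoundaryError("no breakpoint: identity never collapses inside interval")

    coord = lo + int(apos[boundary_col])
    indel = None
    k = boundary_col + 1
    while k < match.size:
        if apos[k] == -1 or bpos[k] == -1:
            length = 0
            kind = "deletion_in_a" if apos[k] == -1 else "insertion_in_a"
            while k < match.size and (apos[k] == -1 if kind == "deletion_in_a" else bpos[k] == -1):
                length += 1
                k += 1
            indel = {"kind": kind, "length": length}
            break
        k += 1
    return BoundaryCall(method="identity", coordinate=coord, interval=(lo, hi),
                        support={"first_post_boundary_indel": indel,
                                 "alignment_score": float(aln.score)})


def _as_depth_array(track) -> np.ndarray:
    if isinstance(track, np.ndarray):
        return track.astype(float)
    # 3-column TSV / BED-graph-like: chrom, pos, depth
    import pandas as pd

    df = pd.read_csv(track, sep="\t", header=None, names=["chrom", "pos", "depth"])
    out = np.zeros(int(df["pos"].max()), dtype=float)
    out[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return out


def _last_sustained(ok: np.ndarray, run_len: int) -> int | None:
    """Last 1-based position p such that ok holds on (p-run_len, p]."""
    if ok.size < run_len:
        return None
    kernel = np.convolve(ok.astype(int), np.ones(run_len, dtype=int), mode="valid")
    hits = np.nonzero(kernel == run_len)[0]
    if hits.size == 0:
        return None
    return int(hits[-1]) + run_len  # 1-based end of the run window


def coverage_boundary(female_depth, male_depth, frac_median: float = 0.1,
                      run_len: int = 200) -> BoundaryCall:
    """PAB from the termination of female read depth on the Y.

    The boundary is the last position where female depth stays at or above
    ``frac_median`` x the chromosome-median female depth for at least
    ``run_len`` bases upstream. The male track is the control: if male depth
    terminates at essentially the same relative point, the signal indicates
    assembly truncation rather than a pseudoautosomal boundary and the call
    is rejected (BoundaryRejected).
    """
    fem = _as_depth_array(female_depth)
    mal = _as_depth_array(male_depth)
    # Reference depth = median female depth over the female-covered region.
    # (A chromosome that is mostly male-specific has a zero chromosome-wide
    # median female depth, so the covered-region median is the usable
    # analogue; the male-track median delimits "covered".)
    med_male = float(np.median(mal))
    covered = fem > (frac_median * med_male if med_male > 0 else 0.0)
    if not covered.any():
        raise BoundaryError("no female signal: no covered bases on this chromosome")
    med = float(np.median(fem[covered]))
    if med <= 0:
        raise BoundaryError("no female signal: covered-region median depth is 0")
    thr = frac_median * med
    boundary = _last_sustained(fem >= thr, run_len)
    if boundary is None:
        raise BoundaryError("no female signal: depth never sustained above threshold")

    med_m = float(np.median(mal))
    male_end = _last_sustained(mal >= frac_median * med_m, run_len) if med_m > 0 else None
    n = fem.size
    if male_end is None or male_end < 0.99 * n:
        raise BoundaryRejected(
            "male control depth also terminates "
            f"(male end {male_end}, chromosome {n} bp): assembly truncation, not a PAB")

    below = fem < thr
    after = below[boundary:]
    drop = np.nonzero(np.convolve(after.astype(int), np.ones(run_len, dtype=int),
                                  mode="valid") == run_len)[0]
    hi = boundary + (int(drop[0]) + run_len) if drop.size else n
    return BoundaryCall(method="coverage", coordinate=boundary,
                        interval=(boundary, hi),
                        support={"female_median": med, "threshold": thr,
                                 "male_end": male_end})


# ---------------------------------------------------------------------------
# telomere arrays


def _best_unit_run(div: np.ndarray, bound: float) -> tuple[int, int] | None:
    """Maximum-score unit run, score = sum(bound - div) (Kadane; ties prefer
    the longer run).

    The maximal run has two useful properties: its mean divergence is <=
    ``bound``, and any unit adjacent to either edge has divergence >= bound
    (otherwise including it would raise the score) — so extending the call
    by one motif unit violates the divergence bound.
    """
    x = bound - div
    eps = 1e-12
    best_sum, best = 0.0, None
    cur, start = 0.0, 0
    for i, xi in enumerate(x):
        if cur < -eps:
            cur, start = 0.0, i
        cur += xi
        length = i + 1 - start
        if (cur > best_sum + eps
                or (cur >= best_sum - eps and (best is None or length > best[1] - best[0]))):
            best_sum, best = max(cur, best_sum), (start, i + 1)
    if best is not None and div[best[0]:best[1]].mean() > bound + eps:
        return None
    return best


def find_telomere(seq, motif: str = "CCCTAA", max_divergence: float = 0.1,
                  search_window: int = 50_000, min_units: int = 2) -> TelomereCall | None:
    """Maximal tandem-motif array within ``search_window`` of either end.

    All phases of the motif and of its reverse complement are tried. The
    call is the maximum-score unit run (score per unit = max_divergence -
    unit divergence), extended by exact partial-unit matches at the edges;
    its mean divergence is <= ``max_divergence`` and it is maximal in the
    sense that the motif unit adjacent to either edge diverges by at least
    ``max_divergence``, so one-unit extension violates the bound. Returns
    None when no array qualifies.
    """
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    s = str(seq).upper()
    k = len(motif)
    best: TelomereCall | None = None
    for offset0, region in ((0, s[:search_window]),
                            (max(0, len(s) - search_window), s[len(s) - search_window:] if len(s) > search_window else s)):
        r = np.frombuffer(region.encode(), np.uint8)
        for m in (motif, revcomp(motif)):
            mcodes = np.frombuffer(m.encode(), np.uint8)
            for phase in range(k):
                n_units = (r.size - phase) // k
                if n_units < min_units:
                    continue
                units = r[phase:phase + n_units * k].reshape(n_units, k)
                div = (units != mcodes).mean(axis=1)
                span = _best_unit_run(div, max_divergence)
                if span is None or span[1] - span[0] < min_units:
                    continue
                i, j = span
                rel_start = phase + i * k
                rel_end = phase + j * k  # half-open, region-relative
                # extend by exact partial-unit matches at either edge
                while rel_end < r.size and region[rel_end] == m[(rel_end - rel_start) % k]:
                    rel_end += 1
                while rel_start > 0 and region[rel_start - 1] == m[(rel_start - 1 - phase - i * k) % k]:
                    rel_start -= 1
                start0 = offset0 + rel_start
                length = rel_end - rel_start
                call = TelomereCall(motif=m, start=start0 + 1, end=start0 + length,
                                    length=length,
                                    divergence=float(div[i:j].mean()))
                if best is None or call.length > best.length:
                    best = call
    return best


# ---------------------------------------------------------------------------
# alignment shift histogram


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    aln_len: int
    mapq: int


def parse_paf(text: str) -> list[PafRecord]:
    recs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"malformed PAF record: {line[:80]!r}")
        recs.append(PafRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                              f[5], int(f[6]), int(f[7]), int(f[8]),
                              int(f[9]), int(f[10]), int(f[11])))
    return recs


@dataclass
class ShiftProfile:
    shifts: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    total_aligned: int
    collinear: bool

    @property
    def n(self) -> int:
        return int(self.shifts.size)


def alignment_shift_profile(alignments, bin_size: int = 5_000,
                            collinear_limit: int = 50_000) -> ShiftProfile:
    """Histogram of per-alignment start shifts (ref start - query start).

    A pair is called collinear when every absolute shift stays at or below
    ``collinear_limit`` (0.05 Mb by default).
    """
    if isinstance(alignments, str):
        alignments = parse_paf(alignments)
    shifts = np.array([r.tstart - r.qstart for r in alignments], dtype=float)
    total = int(sum(r.aln_len for r in alignments))
    if shifts.size == 0:
        return ShiftProfile(shifts, np.array([0.0]), np.array([], dtype=int), 0, True)
    lo = np.floor(shifts.min() / bin_size) * bin_size
    hi = np.ceil(shifts.max() / bin_size) * bin_size + bin_size
    edges = np.arange(lo, hi + 1, bin_size)
    counts, edges = np.histogram(shifts, bins=edges)
    return ShiftProfile(shifts=shifts, bin_edges=edges, counts=counts,
                        total_aligned=total,
                        collinear=bool(np.all(np.abs(shifts) <= collinear_limit)))
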