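"""Depth-voted consensus extraction from a pan-chromosome graph.

A representative linear Y sequence is derived from a GFA1 graph built around
a backbone assembly: contig walks from each sampled individual give every
segment a sample-support depth; within each local divergence/reconvergence
structure (bubble) the branch with the deeper mean depth is preferred, ties
resolving to the backbone; complex regions fall back to the backbone and are
flagged for manual review. A terminal-overlap merge then attaches the
PAR-bearing contig to the exported consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._util import revcomp


class GFAError(ValueError):
    pass


class MergeError(ValueError):
    pass


OrientedSeg = tuple[str, str]  # (segment name, '+'/'-')


@dataclass
class PanGraph:
    segments: dict[str, str]
    links: list[tuple[str, str, str, str]]
    backbone: list[OrientedSeg] = field(default_factory=list)
    depth: dict[str, int] = field(default_factory=dict)
    paths: dict[str, list[OrientedSeg]] = field(default_factory=dict)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.segments)
        for a, _ao, b, _bo in self.links:
            g.add_edge(a, b)
        return g


@dataclass
class Bubble:
    source: OrientedSeg
    sink: OrientedSeg
    branches: list[list[OrientedSeg]]  # internal segments, source/sink excluded
    complex: bool = False


@dataclass
class ConsensusPath:
    path: list[OrientedSeg]
    per_bubble_choice: dict[int, int]
    flags: list[int]  # indices of bubbles needing manual inspection
    sequence: str = ""


def parse_gfa(text: str, backbone: str | None = "backbone") -> PanGraph:
    """Parse GFA1 with explicit sequences (S, L, and P lines).

    The dialect requires sequences on S lines ('*' is rejected). P lines are
    collected into ``paths``; the path named by ``backbone`` (if present)
    becomes the graph's backbone walk.
    """
    segments: dict[str, str] = {}
    links: list[tuple[str, str, str, str]] = []
    paths: dict[str, list[OrientedSeg]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line[0] in "H#":
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "S":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: malformed S line")
            name, seq = fields[1], fields[2]
            if seq == "*":
                raise GFAError(f"line {lineno}: sequence required for segment {name}")
            segments[name] = seq.upper()
        elif fields[0] == "L":
            if len(fields) < 5:
                raise GFAError(f"line {lineno}: malformed L line")
            a, ao, b, bo = fields[1:5]
            for seg in (a, b):
                if seg not in segments:
                    raise GFAError(f"line {lineno}: link references unknown segment {seg}")
            links.append((a, ao, b, bo))
        elif fields[0] == "P":
            name, steps = fields[1], fields[2]
            path = [(s[:-1], s[-1]) for s in steps.split(",") if s]
            for seg, _o in path:
                if seg not in segments:
                    raise GFAError(f"line {lineno}: path references unknown segment {seg}")
            paths[name] = path
    g = PanGraph(segments=segments, links=links, paths=paths)
    if backbone and backbone in paths:
        g.backbone = paths[backbone]
    return g


def write_gfa(graph: PanGraph) -> str:
    lines = ["H\tVN:Z:1.0"]
    for name in sorted(graph.segments):
        lines.append(f"S\t{name}\t{graph.segments[name]}")
    for a, ao, b, bo in graph.links:
        lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M")
    for name, path in graph.paths.items():
        lines.append(f"P\t{name}\t" + ",".join(s + o for s, o in path) + "\t*")
    return "\n".join(lines) + "\n"


def parse_walks(text: str):
    """Parse sample walks from GAF or from the 2-column sample/path TSV.

    Returns a list of ``(sample_name, [segment name, ...])``. GAF is
    recognized by its >= 12 tab-separated columns with the oriented path in
    column 6; the TSV form has the oriented path in column 2.
    """
    walks = []
    for line in text.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) >= 12:
            name, path_str = fields[0], fields[5]
        elif len(fields) == 2:
            name, path_str = fields
        else:
            raise ValueError(f"unrecognized walk record: {line[:80]!r}")
        segs = [s for s in path_str.replace("<", ">").split(">") if s]
        walks.append((name, segs))
    return walks


def segment_depth(graph: PanGraph, walks) -> dict[str, int]:
    """depth[s] = number of distinct samples whose walk covers segment s."""
    if isinstance(walks, str):
        walks = parse_walks(walks)
    covered: dict[str, set[str]] = {s: set() for s in graph.segments}
    for sample, segs in walks:
        for seg in segs:
            if seg not in graph.segments:
                raise GFAError(f"walk {sample!r} references unknown segment {seg}")
            covered[seg].add(sample)
    depth = {s: len(v) for s, v in covered.items()}
    graph.depth = depth
    return depth


def detect_bubbles(graph: PanGraph, cap: int = 64) -> list[Bubble]:
    """Find minimal divergence/reconvergence structures against the backbone.

    Off-backbone segments are grouped into weakly connected components; a
    component hanging between exactly one backbone source and one downstream
    backbone sink forms a bubble whose branches are the simple source->sink
    paths through it plus the backbone's own sub-path. Components with more
    attachment points, internal cycles, or more than ``cap`` branches are
    flagged complex (resolved to the backbone at voting time). Direct
    backbone skip edges contribute an empty (deletion) branch.
    """
    if not graph.backbone:
        raise GFAError("graph has no designated backbone")
    bb_names = [s for s, _o in graph.backbone]
    bb_index = {s: i for i, s in enumerate(bb_names)}
    g = graph.digraph()

    found: dict[tuple[str, str], Bubble] = {}

    def backbone_branch(i: int, j: int) -> list[OrientedSeg]:
        return list(graph.backbone[i + 1:j])

    def add_bubble(i: int, j: int, branches, complex_flag):
        key = (bb_names[i], bb_names[j])
        bb = backbone_branch(i, j)
        if key not in found:
            found[key] = Bubble(source=graph.backbone[i], sink=graph.backbone[j],
                                branches=[bb], complex=False)
        bub = found[key]
        for br in branches:
            if br not in bub.branches:
                bub.branches.append(br)
        bub.complex = bub.complex or complex_flag

    # deletion branches: direct edges that skip backbone segments
    for a, b in g.edges():
        if a in bb_index and b in bb_index and bb_index[b] > bb_index[a] + 1:
            add_bubble(bb_index[a], bb_index[b], [[]], False)

    off = [n for n in g.nodes if n not in bb_index]
    sub = g.subgraph(off)
    for comp in nx.weakly_connected_components(sub):
        comp = set(comp)
        sources = {a for n in comp for a in g.predecessors(n) if a in bb_index}
        sinks = {b for n in comp for b in g.successors(n) if b in bb_index}
        cyclic = not nx.is_directed_acyclic_graph(g.subgraph(comp))
        if len(sources) == 1 and len(sinks) == 1 and not cyclic:
            (src,), (snk,) = sources, sinks
            i, j = bb_index[src], bb_index[snk]
            if i < j:
                branches = []
                over_cap = False
                for path in nx.all_simple_paths(g, src, snk):
                    internal = path[1:-1]
                    if internal and all(n in comp for n in internal):
                        branches.append([(n, "+") for n in internal])
                        if len(branches) > cap:
                            over_cap = True
                            break
                add_bubble(i, j, [] if over_cap else branches, over_cap)
                continue
        # cyclic region, or attachments too tangled -> complex, not an exception
        anchor_is = sorted(bb_index[s] for s in sources | sinks)
        if len(anchor_is) >= 2:
            add_bubble(anchor_is[0], anchor_is[-1], [], True)
    return sorted(found.values(), key=lambda b: bb_index[b.source[0]])


def vote_path(graph: PanGraph, depth: dict[str, int] | None = None,
              bubbles: list[Bubble] | None = None,
              tie: str = "backbone") -> ConsensusPath:
    """Choose, per bubble, the branch with maximal mean segment depth.

    Branch score = mean depth over the branch's segments (robust to how
    finely a branch happens to be segmented); an empty deletion branch
    carries no per-segment support and scores 0. Ties go to the backbone
    branch. Complex bubbles resolve to the backbone and are flagged for
    manual review. The chosen path is concatenated into one sequence,
    reverse-complementing '-' oriented segments.
    """
    if not graph.backbone:
        raise GFAError("graph has no designated backbone")
    bb_names = [s for s, _o in graph.backbone]
    g = graph.digraph()
    for a, b in zip(bb_names, bb_names[1:]):
        if not g.has_edge(a, b) and not _reachable_off_backbone(g, a, b, set(bb_names)):
            raise GFAError(f"backbone disconnected between {a} and {b}")
    if depth is None:
        depth = graph.depth or {s: 0 for s in graph.segments}
    if bubbles is None:
        bubbles = detect_bubbles(graph)

    bb_index = {s: i for i, s in enumerate(bb_names)}
    choice: dict[int, int] = {}
    flags: list[int] = []
    replacement: dict[int, tuple[int, list[OrientedSeg]]] = {}  # start idx -> (end idx, segs)
    for k, bub in enumerate(bubbles):
        i, j = bb_index[bub.source[0]], bb_index[bub.sink[0]]
        backbone_br = list(graph.backbone[i + 1:j])
        if bub.complex:
            choice[k] = bub.branches.index(backbone_br) if backbone_br in bub.branches else 0
            flags.append(k)
            continue
        def score(branch):
            if not branch:
                return 0.0
            return float(np.mean([depth.get(s, 0) for s, _o in branch]))
        scores = [score(br) for br in bub.branches]
        top = max(scores)
        if backbone_br in bub.branches and scores[bub.branches.index(backbone_br)] == top:
            best = bub.branches.index(backbone_br)
        else:
            best = int(np.argmax(scores))
        choice[k] = best
        if bub.branches[best] != backbone_br:
            replacement[i] = (j, bub.branches[best])

    path: list[OrientedSeg] = []
    i = 0
    while i < len(graph.backbone):
        if i in replacement:
            j, segs = replacement[i]
            path.append(graph.backbone[i])
            path.extend(segs)
            i = j
        else:
            path.append(graph.backbone[i])
            i += 1

    seq = "".join(graph.segments[s] if o == "+" else revcomp(graph.segments[s])
                  for s, o in path)
    return ConsensusPath(path=path, per_bubble_choice=choice, flags=flags, sequence=seq)


def _reachable_off_backbone(g, a, b, bb: set) -> bool:
    seen, stack = set(), [a]
    while stack:
        n = stack.pop()
        for nxt in g.successors(n):
            if nxt == b:
                return True
            if nxt not in seen and nxt not in bb:
                seen.add(nxt)
                stack.append(nxt)
    return False


# ---------------------------------------------------------------------------
# terminal-overlap contig merge


def _identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    return float((x == y).mean())


def merge_overlap(seq_a: str, seq_b: str, min_overlap: int = 1_000,
                  min_identity: float = 0.95) -> tuple[str, dict]:
    """Merge two contigs by their best suffix(a)/prefix(b) overlap.

    Both the forward and the reverse-complement orientation of ``seq_b`` are
    tried, as is full containment of b within a. Gap-free overlap scoring is
    exact under the package's substitution-only divergence model. Raises
    MergeError("no merge anchor") rather than silently concatenating.
    """
    a = str(seq_a).upper()
    b = str(seq_b).upper()
    if not a or not b:
        raise MergeError("empty input sequence")

    candidates = []  # (matches, overlap_len, identity, orientation, merged)
    for orient, bb in (("+", b), ("-", revcomp(b))):
        if bb in a:
            candidates.append((len(bb), len(bb), 1.0, orient, a))
            continue
        max_ov = min(len(a), len(bb))
        for ov in range(max_ov, min_overlap - 1, -1):
            ident = _identity(a[-ov:], bb[:ov])
            if ident >= min_identity:
                candidates.append((ident * ov, ov, ident, orient, a + bb[ov:]))
                break  # longest qualifying overlap for this orientation
    if not candidates:
        raise MergeError("no merge anchor: no suffix/prefix overlap "
                         f">= {min_overlap} bp at identity >= {min_identity}")
    matches, ov, ident, orient, merged = max(candidates)
    report = {
        "overlap_len": ov,
        "identity": round(ident, 4),
        "orientation": orient,
        "len_a": len(a),
        "len_b": len(b),
        "merged_len": len(merged),
        "containment": merged == a,
    }
    return merged, report
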