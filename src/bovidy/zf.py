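"""C2H2 zinc-finger array parsing and DNA-binding motif prediction.

PRDM9's DNA-binding domain is a tandem array of C2H2 zinc fingers; each
finger docks in the major groove and reads ~3 bp through four base-contacting
residues at recognition-helix positions -1, 2, 3, and 6. The pipeline here:

1. ``find_zf_domains`` — locate all C-x(2,4)-C-x(12)-H-x(3,5)-H matches in a
   protein and extract the contact residues (fixed offsets from the second
   cysteine);
2. ``score_and_filter`` — score each finger from a per-residue base-affinity
   table and flag fingers below threshold as atypical / non-binding (the
   SET-adjacent early finger of bovine PRDM9 is the canonical casualty);
3. ``assemble_pwm`` — convert per-contact affinities into per-column base
   probabilities (temperature-parameterized exponential normalization) and
   concatenate the active fingers' 3-bp subsites in reverse array order
   (the C-terminal finger binds the 5' end), with a one-base overlap from
   contact residue 2, giving a motif of 3n + 1 bp;
4. ``consensus_motif`` — per-column IUPAC consensus and base composition.

Finger counts, motif lengths, and PWM algebra are exact consequences of the
array; the per-base probabilities inherit the approximate recognition table
(see ``data/zf_recognition.tsv``) and should be treated as qualitative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

BASES = "ACGT"
_C2H2 = re.compile(r"C.{2,4}?C.{12}H.{3,5}?H")

# contact positions -1, 2, 3, 6 of the recognition helix as 1-based offsets
# into the 12-residue spacer that follows the second cysteine
_CONTACT_OFFSETS = (5, 8, 9, 12)  # helix -1, 2, 3, 6
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


class ZFError(ValueError):
    pass


@dataclass
class ZincFinger:
    index: int  # position in the array, 0-based
    start: int  # 1-based residue positions, inclusive
    end: int
    sequence: str
    contact_residues: str  # helix positions -1, 2, 3, 6 in that order
    zf_score: float = 0.0
    active: bool = False


@dataclass
class BindingPWM:
    columns: np.ndarray  # shape (length, 4), rows sum to 1

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])


def load_recognition_table(path=None) -> dict[str, np.ndarray]:
    """Residue -> affinity 4-vector over A,C,G,T. Defaults to the packaged
    table; pass a path to substitute an experimentally derived one."""
    if path is None:
        text = (resources.files("bovidy") / "data" / "zf_recognition.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        aa, *vals = line.split("\t")
        table[aa] = np.array([float(v) for v in vals], dtype=float)
    return table


def find_zf_domains(protein: str) -> list[ZincFinger]:
    """All C2H2 matches (C-x(2,4)-C-x(12)-H-x(3,5)-H) in array order.

    Contact residues are taken at fixed spacer offsets from the second
    cysteine (helix positions -1, 2, 3, 6). Lazy quantifiers keep each match
    minimal; matches are non-overlapping, scanned left to right.
    """
    if not protein:
        raise ZFError("empty protein sequence")
    prot = str(protein).upper()
    fingers = []
    for i, m in enumerate(_C2H2.finditer(prot)):
        seq = m.group(0)
        # locate the second cysteine inside the match (first C is position 0)
        c2 = seq.index("C", 1)
        contacts = "".join(seq[c2 + off] for off in _CONTACT_OFFSETS)
        fingers.append(ZincFinger(index=i, start=m.start() + 1, end=m.end(),
                                  sequence=seq, contact_residues=contacts))
    return fingers


def score_and_filter(fingers: list[ZincFinger],
                     recognition_table: dict[str, np.ndarray] | None = None,
                     score_threshold: float = 0.5,
                     evalues: dict[int, float] | None = None,
                     max_evalue: float | None = None) -> list[ZincFinger]:
    """Score each finger and flag the active (DNA-binding-competent) ones.

    zf_score is the mean, over the four contact residues, of the residue's
    best base affinity — a [0, 1] measure of how decisively the finger can
    prefer any base at each of its contacts. ``active`` requires
    zf_score >= ``score_threshold``; when externally computed HMM e-values
    are supplied via ``evalues`` (finger index -> e-value), fingers above
    ``max_evalue`` are additionally deactivated.
    """
    table = recognition_table or load_recognition_table()
    for f in fingers:
        affs = []
        for aa in f.contact_residues:
            if aa not in table:
                raise ZFError(f"contact residue {aa!r} not in recognition table")
            affs.append(float(table[aa].max()))
        f.zf_score = float(np.mean(affs))
        f.active = f.zf_score >= score_threshold
        if evalues is not None and max_evalue is not None:
            if evalues.get(f.index, 0.0) > max_evalue:
                f.active = False
    return fingers


def _column_probs(aff: np.ndarray, temperature: float) -> np.ndarray:
    w = np.exp(aff / temperature)
    return w / w.sum()


def assemble_pwm(fingers: list[ZincFinger],
                 recognition_table: dict[str, np.ndarray] | None = None,
                 temperature: float = 0.2) -> BindingPWM:
    """Assemble the predicted binding PWM from the active fingers.

    Fingers are laid down in reverse array order (the C-terminal finger
    reads the 5' end of the site). Each finger contributes a 3-bp subsite
    from contact residues at helix positions 6, 3, -1 (5'->3'), and its
    position-2 residue contacts the base immediately 3' of the subsite —
    the first base of the next subsite (probabilities averaged) or, for the
    final finger laid down, one extra trailing column. Motif length is
    therefore 3n + 1 for n active fingers.
    """
    table = recognition_table or load_recognition_table()
    active = [f for f in fingers if f.active]
    if not active:
        raise ZFError("zero active fingers: no PWM to assemble")
    cols: list[np.ndarray] = []
    overlap: np.ndarray | None = None
    for f in reversed(active):
        aff_m1, aff_p2, aff_p3, aff_p6 = (table[aa] for aa in f.contact_residues)
        triplet = [_column_probs(aff_p6, temperature),
                   _column_probs(aff_p3, temperature),
                   _column_probs(aff_m1, temperature)]
        if overlap is not None:
            triplet[0] = (triplet[0] + overlap) / 2.0
        cols.extend(triplet)
        overlap = _column_probs(aff_p2, temperature)
    cols.append(overlap)
    pwm = BindingPWM(columns=np.vstack(cols))
    assert np.allclose(pwm.columns.sum(axis=1), 1.0)
    return pwm


def consensus_motif(pwm: BindingPWM, tie_margin: float = 0.05) -> tuple[str, dict]:
    """Per-column IUPAC consensus plus a ranked base-composition summary.

    A column's consensus includes every base whose probability is within
    ``tie_margin`` of the column maximum (IUPAC ambiguity codes; a flat
    column becomes N).
    """
    letters = []
    top_bases = []
    for col in pwm.columns:
        top = col.max()
        members = frozenset(BASES[i] for i in range(4) if col[i] >= top - tie_margin)
        letters.append(_IUPAC[members])
        top_bases.append(BASES[int(col.argmax())])
    comp = {b: top_bases.count(b) for b in BASES}
    ranked = sorted(comp.items(), key=lambda kv: (-kv[1], kv[0]))
    return "".join(letters), {"counts": comp, "ranked": [b for b, _ in ranked]}


def pwm_to_meme(pwm: BindingPWM, name: str = "motif") -> str:
    """Minimal MEME motif format."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "strands: + -", "",
             "Background letter frequencies",
             "A 0.25 C 0.25 G 0.25 T 0.25", "",
             f"MOTIF {name}",
             f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0"]
    for col in pwm.columns:
        lines.append(" ".join(f"{p:.6f}" for p in col))
    return "\n".join(lines) + "\n"


def pwm_to_tsv(pwm: BindingPWM) -> str:
    lines = ["pos\tA\tC\tG\tT"]
    for i, col in enumerate(pwm.columns, 1):
        lines.append(f"{i}\t" + "\t".join(f"{p:.6f}" for p in col))
    return "\n".join(lines) + "\n"


# convenience constructors for canonical test arrays -------------------------


def canonical_finger(contacts: str = "RDHR", linker: str = "TGEKPYE") -> str:
    """One canonical C2H2 finger peptide with the given contact residues at
    helix positions -1, 2, 3, 6, followed by a linker."""
    m1, p2, p3, p6 = contacts
    spacer = ["S"] * 12
    spacer[_CONTACT_OFFSETS[0] - 1] = m1
    spacer[_CONTACT_OFFSETS[1] - 1] = p2
    spacer[_CONTACT_OFFSETS[2] - 1] = p3
    spacer[_CONTACT_OFFSETS[3] - 1] = p6
    return "CAEC" + "".join(spacer) + "HIRTH" + linker


def tandem_array(n: int, contacts: str = "RDHR", degenerate_first: bool = False) -> str:
    """A protein with ``n`` tandem canonical fingers (plus an optional
    degenerate SET-adjacent finger at the front, as in bovine PRDM9)."""
    fingers = [canonical_finger(contacts) for _ in range(n)]
    if degenerate_first:
        fingers.insert(0, canonical_finger("PGAS"))
    return "MAST" + "".join(fingers) + "STOPFREE"
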