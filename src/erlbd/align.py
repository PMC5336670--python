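"""Global pairwise sequence alignment and conservation statistics.

Needleman–Wunsch with affine gap penalties (Gotoh's three-state
recursion).  A gap of length L costs ``gap_open + (L - 1) * gap_extend``,
i.e. the opening residue pays the full opening penalty and each further
gapped residue pays the extension penalty.  Substitution matrices come
from Biopython's collection (BLOSUM62 by default).

Percent identity and percent similarity are computed over alignment
columns; the default denominator is the number of columns where neither
sequence is gapped (configurable to the full alignment length).
Similarity uses the classic strongly-conserved residue groups
(STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import substitution_matrices

from .errors import ConfigurationError, ValidationError
from .structures import AA_ALPHABET, SequenceRecord

GAP = "-"

#: Strong conservation groups (approximation of classic CLUSTAL practice).
STRONG_GROUPS: tuple[str, ...] = (
    "STA",
    "NEQK",
    "NHQK",
    "NDEQ",
    "QHRK",
    "MILV",
    "MILF",
    "HY",
    "FYW",
)

#: Denominator conventions for the percentage statistics.
DENOMINATORS = ("nongap", "columns")

_MATRIX_CACHE: dict[str, object] = {}


def load_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix (cached)."""
    key = name.upper()
    if key not in _MATRIX_CACHE:
        try:
            _MATRIX_CACHE[key] = substitution_matrices.load(key)
        except FileNotFoundError as exc:
            raise ConfigurationError(f"unknown substitution matrix {name!r}") from exc
    return _MATRIX_CACHE[key]


@dataclass(frozen=True)
class AlignmentResult:
    """A gapped global alignment of two sequences plus summary statistics."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    n_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")
        if self.n_columns != len(self.aligned_a):
            raise ValidationError("n_columns inconsistent with aligned strings")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)

    def degapped(self) -> tuple[str, str]:
        return (self.aligned_a.replace(GAP, ""), self.aligned_b.replace(GAP, ""))

    def csv_row(self) -> str:
        return (
            f"{self.id_a},{self.id_b},{self.identity_pct:.2f},"
            f"{self.similarity_pct:.2f},{self.score:g}"
        )

    def pretty(self, width: int = 60) -> str:
        """Plain-text pairwise block with a midline marking conservation."""
        mid = []
        groups = [set(g) for g in STRONG_GROUPS]
        for x, y in self.columns():
            if x == y and x != GAP:
                mid.append("|")
            elif x != GAP and y != GAP and any(x in g and y in g for g in groups):
                mid.append(":")
            else:
                mid.append(" ")
        midline = "".join(mid)
        blocks = []
        for i in range(0, self.n_columns, width):
            blocks.append(
                "\n".join(
                    (
                        f"{self.id_a[:12]:<12} {self.aligned_a[i:i + width]}",
                        f"{'':<12} {midline[i:i + width]}",
                        f"{self.id_b[:12]:<12} {self.aligned_b[i:i + width]}",
                    )
                )
            )
        header = (
            f"# score={self.score:g} identity={self.identity_pct:.1f}% "
            f"similarity={self.similarity_pct:.1f}% columns={self.n_columns}"
        )
        return header + "\n" + "\n\n".join(blocks) + "\n"


def _as_record(seq, default_id: str) -> SequenceRecord:
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord(default_id, str(seq))


def align_global(
    a,
    b,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    groups: Sequence[str] = STRONG_GROUPS,
    denominator: str = "nongap",
) -> AlignmentResult:
    """Optimal global alignment of two sequences with affine gap penalties.

    Penalties are positive numbers (subtracted from the score).  Among
    co-optimal alignments the traceback deterministically prefers a
    substitution over a gap in the second sequence over a gap in the
    first.  Returns an :class:`AlignmentResult` carrying the optimal
    score and the identity/similarity percentages.
    """
    ra, rb = _as_record(a, "a"), _as_record(b, "b")
    sub = load_matrix(matrix)
    sa, sb = ra.residues, rb.residues
    n, m = len(sa), len(sb)
    NEG = float("-inf")

    # Gotoh three-state DP.  M: column with residues in both sequences;
    # X: gap in b (consumes a); Y: gap in a (consumes b).
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)

    # traceback pointers: state entered from, per cell and state
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PX = [[0] * (m + 1) for _ in range(n + 1)]
    PY = [[0] * (m + 1) for _ in range(n + 1)]
    STATES = (0, 1, 2)  # M, X, Y — priority order for ties

    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if i > 0 and j > 0:
                s = float(sub[sa[i - 1], sb[j - 1]])
                cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                k = max(STATES, key=lambda st: (cands[st], -st))
                M[i][j] = s + cands[k]
                PM[i][j] = k
            if i > 0:
                cands = (
                    M[i - 1][j] - gap_open,
                    X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open,
                )
                k = max(STATES, key=lambda st: (cands[st], -st))
                X[i][j] = cands[k]
                PX[i][j] = k
            if j > 0:
                cands = (
                    M[i][j - 1] - gap_open,
                    X[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend,
                )
                k = max(STATES, key=lambda st: (cands[st], -st))
                Y[i][j] = cands[k]
                PY[i][j] = k

    finals = (M[n][m], X[n][m], Y[n][m])
    state = max(STATES, key=lambda st: (finals[st], -st))
    score = finals[state]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            state = PM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            state = PX[i][j]
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            state = PY[i][j]
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    result = AlignmentResult(
        id_a=ra.id,
        id_b=rb.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=0.0,
        similarity_pct=0.0,
        n_columns=len(aligned_a),
    )
    ident = percent_identity(result, denominator=denominator)
    simil = percent_similarity(result, groups=groups, denominator=denominator)
    return AlignmentResult(
        id_a=ra.id,
        id_b=rb.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=ident,
        similarity_pct=simil,
        n_columns=len(aligned_a),
    )


def _denominator(result: AlignmentResult, convention: str) -> int:
    if convention == "columns":
        return result.n_columns
    if convention == "nongap":
        return sum(1 for x, y in result.columns() if x != GAP and y != GAP)
    raise ConfigurationError(
        f"unknown denominator {convention!r}; expected one of {DENOMINATORS}"
    )


def percent_identity(result: AlignmentResult, denominator: str = "nongap") -> float:
    """Percentage of columns with identical residues in both sequences."""
    denom = _denominator(result, denominator)
    if denom == 0:
        return 0.0
    ident = sum(1 for x, y in result.columns() if x == y and x != GAP)
    return 100.0 * ident / denom


def percent_similarity(
    result: AlignmentResult,
    groups: Sequence[str] = STRONG_GROUPS,
    denominator: str = "nongap",
) -> float:
    """Percentage of columns identical or conservatively substituted.

    A non-identical column counts as similar when both residues co-occur
    in at least one conservation group.
    """
    group_sets = [set(g.upper()) for g in groups]
    for g in group_sets:
        bad = g - set(AA_ALPHABET)
        if bad:
            raise ValidationError(
                f"conservation group contains non-amino-acid codes: {sorted(bad)}"
            )
    denom = _denominator(result, denominator)
    if denom == 0:
        return 0.0
    count = 0
    for x, y in result.columns():
        if x == GAP or y == GAP:
            continue
        if x == y or any(x in g and y in g for g in group_sets):
            count += 1
    return 100.0 * count / denom
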