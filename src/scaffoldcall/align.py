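"""Seed-and-extend affine-gap alignment of read pairs to the scaffold pair.

Each mate is aligned independently to both scaffolds (both orientations) with
exact k-mer seeding followed by an affine-gap Smith-Waterman extension over the
seeded window.  Terminal soft clips are free (clipped bases score 0), which is
exactly the local-alignment optimum, so the heuristic agrees with an exhaustive
local DP wherever seeding finds the optimal window.  The default scoring
(+1 match, -4 mismatch, gap of length g costs 6 + (g - 1)) makes a 68 bp gap
(-73) costlier than four mismatches (-16): reads lacking the insertion are
*forced* into mismatch/soft-clip alignments on the mutant scaffold rather than
opening the long gap, while genuine insertion reads score strictly higher on
the mutant scaffold.  That score competition is what the genotype module
classifies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .reference_model import ScaffoldSet
from .simulate import ReadPair, revcomp

__all__ = [
    "ScoringScheme",
    "Placement",
    "PairPlacement",
    "SeedIndex",
    "build_index",
    "align_read",
    "align_pair",
    "write_sam",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores.  ``gap_open`` is the cost of the first gap base and
    ``gap_extend`` of each additional one, so a gap of length g scores
    ``gap_open + (g - 1) * gap_extend``.  Soft clips are free; ``min_anchor``
    is the minimum number of aligned (M) read bases for a placement to count."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_anchor: int = 25

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("need gap_open <= gap_extend < 0")
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be positive")


_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_kernel(q, r, match, mismatch, gap_open, gap_extend):
    """Local affine-gap DP with full traceback.

    Returns (score, qbeg, qend, rbeg, rend, op_codes, op_lens, n_ops, aligned)
    with 0-based half-open read/ref spans; op codes 0=M, 1=I (read-only),
    2=D (ref-only).  Among equal-scoring cells the first in row-major order is
    kept, giving a deterministic leftmost-end tie-break.
    """
    n = q.shape[0]
    m = r.shape[0]
    NEG = -(10**7)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming ref (D)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming read (I)
    # ptr bits: 0-1 H source (0 stop, 1 diag, 2 E, 3 F); bit2 E-from-E; bit3 F-from-F
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptr[i, j] |= 4
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr[i, j] |= 8
            else:
                F[i, j] = f_open
            sub = match if qi == r[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            h = np.int32(0)
            src = 0
            if diag > h:
                h = diag
                src = 1
            if E[i, j] > h:
                h = E[i, j]
                src = 2
            if F[i, j] > h:
                h = F[i, j]
                src = 3
            H[i, j] = h
            ptr[i, j] |= src
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    op_codes = np.empty(n + m + 2, dtype=np.int8)
    op_lens = np.empty(n + m + 2, dtype=np.int32)
    n_ops = 0
    aligned = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            src = ptr[i, j] & 3
            if src == 0 or H[i, j] == 0:
                break
            if src == 1:
                code = 0
                i -= 1
                j -= 1
                aligned += 1
            elif src == 2:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            code = 2  # D: consumes ref
            from_e = ptr[i, j] & 4
            j -= 1
            state = 1 if from_e else 0
        else:
            code = 1  # I: consumes read
            from_f = ptr[i, j] & 8
            i -= 1
            state = 2 if from_f else 0
        if n_ops > 0 and op_codes[n_ops - 1] == code:
            op_lens[n_ops - 1] += 1
        else:
            op_codes[n_ops] = code
            op_lens[n_ops] = 1
            n_ops += 1
    return int(best), i, bi, j, bj, op_codes, op_lens, n_ops, aligned


@dataclass(frozen=True)
class Placement:
    """One mate's best alignment on one scaffold.

    ``cigar`` uses M/I/D/S run-lengths in read order and consumes the read
    exactly; ``seq``/``qual`` are stored in the aligned orientation."""

    scaffold: str  # "wt" | "mu"
    start: int  # 1-based ref start of the aligned span
    score: int
    cigar: tuple[tuple[str, int], ...]
    strand: str  # "+" forward read, "-" reverse-complemented read
    seq: str
    qual: str

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def max_clip(self) -> int:
        return max(self.left_clip, self.right_clip)

    @property
    def end(self) -> int:
        """1-based inclusive ref end of the aligned span."""
        span = sum(ln for op, ln in self.cigar if op in "MD")
        return self.start + span - 1

    @property
    def aligned_length(self) -> int:
        return sum(ln for op, ln in self.cigar if op == "M")

    def base_at(self, pos: int) -> tuple[str, str] | None:
        """Read base and quality char aligned to reference position ``pos``
        (M columns only; clipped/gapped positions return None)."""
        rp = self.start
        qp = 0
        for op, ln in self.cigar:
            if op == "M":
                if rp <= pos < rp + ln:
                    idx = qp + (pos - rp)
                    return self.seq[idx], self.qual[idx] if self.qual else "I"
                rp += ln
                qp += ln
            elif op == "D":
                if rp <= pos < rp + ln:
                    return None
                rp += ln
            else:  # I or S consume read only
                qp += ln
        return None


@dataclass(frozen=True)
class PairPlacement:
    """Both mates' placements on one scaffold.

    The pair score is the sum over placed mates (an unplaced mate contributes
    nothing); the proper-pair flag requires both mates in FR orientation at a
    plausible insert size."""

    scaffold: str
    mate1: Placement | None
    mate2: Placement | None
    proper: bool = False

    @property
    def score(self) -> int:
        return (self.mate1.score if self.mate1 else 0) + (
            self.mate2.score if self.mate2 else 0
        )

    @property
    def mapped(self) -> bool:
        return self.mate1 is not None or self.mate2 is not None


class SeedIndex:
    """Exact k-mer position index over both scaffolds."""

    def __init__(self, s: ScaffoldSet, k: int = 15, scaffolds: tuple[str, ...] = ("wt", "mu")):
        if k < 8:
            raise ValueError("k < 8 gives unusably unspecific seeds")
        if k > min(len(s.wt), len(s.mu)):
            raise ValueError("k exceeds scaffold length")
        self.k = k
        self.scaffold_set = s
        self.sequences: dict[str, str] = {}
        self.encoded: dict[str, np.ndarray] = {}
        self.tables: dict[str, dict[str, list[int]]] = {}
        names = {"wt": s.wt.sequence, "mu": s.mu.sequence}
        for role in scaffolds:
            seq = names[role]
            self.sequences[role] = seq
            self.encoded[role] = _encode(seq)
            table: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i : i + k], []).append(i)
            self.tables[role] = table

    def lookup(self, role: str, kmer: str) -> list[int]:
        """All 0-based occurrence positions of ``kmer`` on one scaffold."""
        return self.tables[role].get(kmer, [])


def build_index(s: ScaffoldSet, k: int = 15) -> SeedIndex:
    """Build the seed index for competitive alignment to both scaffolds."""
    return SeedIndex(s, k=k)


_SEED_STEP = 10
_WINDOW_PAD = 90
_MAX_DIAG_SPREAD = 220


def _align_oriented(
    seq: str, qual: str, role: str, index: SeedIndex, scheme: ScoringScheme, strand: str
) -> Placement | None:
    k = index.k
    n = len(seq)
    if n < k:
        return None
    ref = index.sequences[role]
    table = index.tables[role]
    positions = list(range(0, n - k + 1, _SEED_STEP))
    if positions[-1] != n - k:
        positions.append(n - k)
    votes: dict[int, int] = {}
    for p in positions:
        for hit in table.get(seq[p : p + k], ()):
            d = hit - p
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    best_d = min(votes, key=lambda d: (-votes[d], d))
    # fast path: full-length exact match at the top diagonal
    if 0 <= best_d <= len(ref) - n and ref[best_d : best_d + n] == seq:
        return Placement(
            scaffold=role,
            start=best_d + 1,
            score=n * scheme.match,
            cigar=(("M", n),),
            strand=strand,
            seq=seq,
            qual=qual,
        )
    diags = [d for d in votes if abs(d - best_d) <= _MAX_DIAG_SPREAD]
    lo = max(0, min(diags) - _WINDOW_PAD)
    hi = min(len(ref), max(diags) + n + _WINDOW_PAD)
    score, qbeg, qend, rbeg, rend, codes, lens, n_ops, aligned = _sw_kernel(
        _encode(seq),
        index.encoded[role][lo:hi],
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extend,
    )
    if aligned < scheme.min_anchor:
        return None
    ops: list[tuple[str, int]] = []
    if qbeg > 0:
        ops.append(("S", qbeg))
    # traceback produced ops end-to-start
    letters = "MID"
    for t in range(n_ops - 1, -1, -1):
        ops.append((letters[codes[t]], int(lens[t])))
    if n - qend > 0:
        ops.append(("S", n - qend))
    return Placement(
        scaffold=role,
        start=lo + rbeg + 1,
        score=score,
        cigar=tuple(ops),
        strand=strand,
        seq=seq,
        qual=qual,
    )


def align_read(
    seq: str,
    index: SeedIndex,
    scheme: ScoringScheme = ScoringScheme(),
    qual: str = "",
) -> dict[str, Placement | None]:
    """Best placement of one read on each indexed scaffold.

    Both orientations are tried; the higher-scoring one wins (forward on
    ties).  A scaffold with no seed hits, or where the best extension aligns
    fewer than ``min_anchor`` read bases, reports ``None`` (unmapped)."""
    seq = seq.upper()
    rc = revcomp(seq)
    rc_qual = qual[::-1]
    out: dict[str, Placement | None] = {}
    for role in index.sequences:
        fwd = _align_oriented(seq, qual, role, index, scheme, "+")
        rev = _align_oriented(rc, rc_qual, role, index, scheme, "-")
        if fwd is None:
            out[role] = rev
        elif rev is None or fwd.score >= rev.score:
            out[role] = fwd
        else:
            out[role] = rev
    return out


def align_pair(
    pair: ReadPair,
    index: SeedIndex,
    scheme: ScoringScheme = ScoringScheme(),
    frag_model: tuple[float, float] | None = (300.0, 100.0),
) -> dict[str, PairPlacement]:
    """Align both mates and pair them per scaffold.

    The proper-pair flag requires opposite strands in FR orientation with an
    insert within mean ± 4 sd of the fragment model; an improper pair keeps
    its score but loses the flag."""
    m1 = align_read(pair.seq1, index, scheme, pair.qual1)
    m2 = align_read(pair.seq2, index, scheme, pair.qual2)
    out: dict[str, PairPlacement] = {}
    for role in index.sequences:
        p1, p2 = m1[role], m2[role]
        proper = False
        if p1 is not None and p2 is not None and p1.strand != p2.strand:
            left, right = (p1, p2) if p1.start <= p2.start else (p2, p1)
            if left.strand == "+" and right.strand == "-":
                insert = right.end - left.start + 1
                if frag_model is None:
                    proper = True
                else:
                    mean, sd = frag_model
                    proper = abs(insert - mean) <= 4 * sd
        out[role] = PairPlacement(scaffold=role, mate1=p1, mate2=p2, proper=proper)
    return out


def write_sam(
    results: list[tuple[ReadPair, dict[str, PairPlacement]]],
    scaffold_set: ScaffoldSet,
    out_prefix: str,
) -> dict[str, str]:
    """Optional SAM export: one file per scaffold with soft clips as S ops,
    MAPQ 60 for pair-strict placements and 0 for cross-scaffold ties."""
    import pysam

    names = {"wt": scaffold_set.wt.name, "mu": scaffold_set.mu.name}
    lengths = {"wt": len(scaffold_set.wt), "mu": len(scaffold_set.mu)}
    paths = {}
    for role in names:
        path = f"{out_prefix}.{role}.sam"
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": names[role], "LN": lengths[role]}],
        }
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for pair, placements in results:
                pp = placements.get(role)
                if pp is None or not pp.mapped:
                    continue
                other = [p for r, p in placements.items() if r != role]
                tied = any(o.mapped and o.score >= pp.score for o in other)
                for mate_i, plc in ((1, pp.mate1), (2, pp.mate2)):
                    if plc is None:
                        continue
                    a = pysam.AlignedSegment()
                    a.query_name = pair.id
                    a.query_sequence = plc.seq
                    a.query_qualities = pysam.qualitystring_to_array(plc.qual) if plc.qual else None
                    a.reference_id = 0
                    a.reference_start = plc.start - 1
                    a.cigarstring = "".join(f"{ln}{op}" for op, ln in plc.cigar)
                    a.mapping_quality = 0 if tied else 60
                    flag = 0x1 | (0x40 if mate_i == 1 else 0x80)
                    if plc.strand == "-":
                        flag |= 0x10
                    if pp.proper:
                        flag |= 0x2
                    a.flag = flag
                    fh.write(a)
        paths[role] = path
    return paths
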