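"""Diploid paired-end read simulation for scaffold-caller validation.

Emulates a short-read screening run over the target region: for a chosen
diploid genotype the two haplotype molecules are built from the wild-type
sequence (optional SNV, optional insertion allele carrying the *natural*
marker base — the engineered scaffold base never occurs in real molecules),
then paired 150 bp reads are sampled at a target fold coverage with
Normal(300, 100) fragment lengths and uniform per-base substitution errors.

The error model is deliberately simple: conclusions of the dual-scaffold
method hinge on allele identity at three informative sites, not on a profiled
instrument error spectrum, so a uniform substitution rate with matching Phred
qualities stands in for a platform-specific profile; indel errors are not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_model import ScaffoldSet

__all__ = [
    "HaplotypeSpec",
    "DiploidGenotype",
    "GENOTYPES",
    "TABLE_GENOTYPE_LABELS",
    "SimParams",
    "ReadPair",
    "make_haplotypes",
    "simulate_pairs",
    "write_fastq",
    "load_fastq_pairs",
    "revcomp",
]

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class HaplotypeSpec:
    """One haplotype of a diploid genotype."""

    has_insertion: bool = False
    has_snv: bool = False
    insertion_allele: str = "common"


@dataclass(frozen=True)
class DiploidGenotype:
    label: str
    haplotypes: tuple[HaplotypeSpec, HaplotypeSpec]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != 2:
            raise ValueError("a diploid genotype has exactly two haplotypes")


def _g(label: str, h1: HaplotypeSpec, h2: HaplotypeSpec) -> DiploidGenotype:
    return DiploidGenotype(label, (h1, h2))


_WT = HaplotypeSpec()
_SNV = HaplotypeSpec(has_snv=True)
_INS = HaplotypeSpec(has_insertion=True)
_CPX = HaplotypeSpec(has_insertion=True, has_snv=True)

#: All supported diploid genotype/phase combinations.  The seven canonical
#: lookup-table rows are reachable through TABLE_GENOTYPE_LABELS; the extra
#: HOM forms exist for reference-bias experiments and collapse onto the same
#: rows as their HET counterparts wherever the table does not resolve dosage.
GENOTYPES: dict[str, DiploidGenotype] = {
    "WT": _g("WT", _WT, _WT),
    "SNV_HET": _g("SNV_HET", _SNV, _WT),
    "SNV_HOM": _g("SNV_HOM", _SNV, _SNV),
    "INS_HET": _g("INS_HET", _INS, _WT),
    "INS_HOM": _g("INS_HOM", _INS, _INS),
    "COMPLEX_HET": _g("COMPLEX_HET", _CPX, _WT),
    "COMPLEX_HOM": _g("COMPLEX_HOM", _CPX, _CPX),
    "SNV_trans_INS": _g("SNV_trans_INS", _SNV, _INS),
    "SNV_trans_COMPLEX": _g("SNV_trans_COMPLEX", _SNV, _CPX),
    "INS_trans_COMPLEX": _g("INS_trans_COMPLEX", _INS, _CPX),
}

#: One simulated genotype per row of the seven-row genotype/phase lookup table.
TABLE_GENOTYPE_LABELS: tuple[str, ...] = (
    "SNV_HET",
    "INS_HET",
    "COMPLEX_HET",
    "SNV_trans_INS",
    "SNV_trans_COMPLEX",
    "INS_trans_COMPLEX",
    "WT",
)


@dataclass(frozen=True)
class SimParams:
    """Simulation settings (defaults mirror a 2x150 screening run)."""

    coverage: float = 200.0
    read_length: int = 150
    fragment_mean: float = 300.0
    fragment_sd: float = 100.0
    base_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length > self.fragment_mean + 4 * self.fragment_sd:
            raise ValueError("read length exceeds plausible fragment sizes")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base error rate must be in [0, 1)")

    @property
    def quality_char(self) -> str:
        """Phred+33 quality consistent with the substitution rate."""
        if self.base_error_rate <= 0:
            return chr(33 + 40)
        q = min(40, int(round(-10 * np.log10(self.base_error_rate))))
        return chr(33 + q)


@dataclass(frozen=True)
class ReadPair:
    """A simulated (or parsed) read pair; truth fields are retained for
    evaluation and are absent (-1) for pairs parsed from FASTQ."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    hap_index: int = -1
    frag_start: int = -1
    frag_end: int = -1


def make_haplotypes(
    s: ScaffoldSet,
    genotype: DiploidGenotype | str,
    rare_insertion=None,
) -> tuple[str, str]:
    """Materialize the two haplotype molecules of a diploid genotype.

    Insertion-bearing haplotypes carry the natural marker base.  A cis-complex
    haplotype carries the SNV alt base *downstream* of the inserted copy (the
    position lifting to the MU cis-image site): biologically, the inserted
    copy retains the wild-type base while the original site mutates.
    """
    if isinstance(genotype, str):
        try:
            genotype = GENOTYPES[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype label {genotype!r}") from None

    def build(h: HaplotypeSpec) -> str:
        wt = s.wt.sequence
        snv_idx = s.snv.wt_position - 1
        if not h.has_insertion:
            if h.has_snv:
                return wt[:snv_idx] + s.snv.alt_base + wt[snv_idx + 1 :]
            return wt
        if h.insertion_allele == "rare":
            if rare_insertion is None:
                raise ValueError("rare insertion allele requested but no spec given")
            copy = list(wt[rare_insertion.source_start - 1 : rare_insertion.source_end])
            for off, base in rare_insertion.divergent_bases:
                copy[off - 1] = base
            insert = "".join(copy)
        else:
            insert = s.natural_insert()
        ip = s.insertion.insertion_point
        seq = wt[: ip - 1] + insert + wt[ip - 1 :]
        if h.has_snv:
            idx = s.sites["mu_cis_snv"] - 1  # cis image, downstream of the copy
            seq = seq[:idx] + s.snv.alt_base + seq[idx + 1 :]
        return seq

    return build(genotype.haplotypes[0]), build(genotype.haplotypes[1])


def simulate_pairs(haplotypes: tuple[str, str], p: SimParams) -> list[ReadPair]:
    """Sample paired-end reads from two haplotypes.

    The pair count is ``round(mean_len * coverage / (2 * read_length))``; each
    fragment picks a haplotype by fair coin, a Normal(mean, sd) length
    (resampled until it fits in ``[read_length, len(hap)]``) and a uniform
    start.  Mate 1 / mate 2 roles are swapped on a random strand flip so both
    orientations occur.  Deterministic for a fixed seed.
    """
    h1, h2 = haplotypes
    rl = p.read_length
    for h in (h1, h2):
        if len(h) < rl:
            raise ValueError("haplotype shorter than the read length")
    lens = np.array([len(h1), len(h2)])
    n = int(round(lens.mean() * p.coverage / (2 * rl)))
    rng = np.random.default_rng(p.seed)

    hap_choice = rng.integers(0, 2, size=n)
    hap_len = lens[hap_choice]
    frag = np.rint(rng.normal(p.fragment_mean, p.fragment_sd, size=n)).astype(np.int64)
    bad = (frag < rl) | (frag > hap_len)
    while bad.any():  # resample, never truncate
        frag[bad] = np.rint(
            rng.normal(p.fragment_mean, p.fragment_sd, size=int(bad.sum()))
        ).astype(np.int64)
        bad = (frag < rl) | (frag > hap_len)
    start = rng.integers(1, hap_len - frag + 2)  # 1-based fragment start
    flip = rng.integers(0, 2, size=n).astype(bool)
    err = rng.random((n, 2, rl)) < p.base_error_rate

    qual = p.quality_char * rl
    haps = (h1, h2)
    pairs: list[ReadPair] = []
    for i in range(n):
        hap = haps[hap_choice[i]]
        s0 = int(start[i]) - 1
        fragment = hap[s0 : s0 + int(frag[i])]
        fwd = fragment[:rl]
        rev = revcomp(fragment[-rl:])
        m1, m2 = (rev, fwd) if flip[i] else (fwd, rev)
        m1 = _mutate(m1, err[i, 0], rng)
        m2 = _mutate(m2, err[i, 1], rng)
        pairs.append(
            ReadPair(
                id=f"sim_{i:06d}",
                seq1=m1,
                qual1=qual,
                seq2=m2,
                qual2=qual,
                hap_index=int(hap_choice[i]),
                frag_start=int(start[i]),
                frag_end=int(start[i] + frag[i] - 1),
            )
        )
    return pairs


_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def _mutate(seq: str, mask: np.ndarray, rng: np.random.Generator) -> str:
    if not mask.any():
        return seq
    out = list(seq)
    for pos in np.flatnonzero(mask):
        shift = int(rng.integers(1, 4))  # random non-identical base
        out[pos] = _BASES[(_BASE_IDX[out[pos]] + shift) % 4]
    return "".join(out)


def write_fastq(pairs: list[ReadPair], prefix: str) -> dict[str, str]:
    """Write mates as ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq`` (Phred+33,
    /1 and /2 suffixes) plus a tab-separated truth sidecar."""
    paths = {
        "r1": f"{prefix}_R1.fastq",
        "r2": f"{prefix}_R2.fastq",
        "truth": f"{prefix}_truth.tsv",
    }
    with open(paths["r1"], "w") as f1, open(paths["r2"], "w") as f2, open(
        paths["truth"], "w"
    ) as ft:
        ft.write("id\thap_index\tfrag_start\tfrag_end\n")
        for pr in pairs:
            f1.write(f"@{pr.id}/1\n{pr.seq1}\n+\n{pr.qual1}\n")
            f2.write(f"@{pr.id}/2\n{pr.seq2}\n+\n{pr.qual2}\n")
            ft.write(f"{pr.id}\t{pr.hap_index}\t{pr.frag_start}\t{pr.frag_end}\n")
    return paths


def load_fastq_pairs(r1_path: str, r2_path: str) -> list[ReadPair]:
    """Read mate-paired FASTQ files back into :class:`ReadPair` objects."""
    import pysam

    pairs = []
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for rec1, rec2 in zip(f1, f2):
            name1 = rec1.name.removesuffix("/1")
            name2 = rec2.name.removesuffix("/2")
            if name1 != name2:
                raise ValueError(f"unpaired FASTQ records: {rec1.name} vs {rec2.name}")
            pairs.append(
                ReadPair(
                    id=name1,
                    seq1=rec1.sequence.upper(),
                    qual1=rec1.quality or "",
                    seq2=rec2.sequence.upper(),
                    qual2=rec2.quality or "",
                )
            )
    return pairs
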