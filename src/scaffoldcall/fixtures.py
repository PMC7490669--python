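"""Synthetic CBS-analog fixture.

The method's canonical use case is the CBS gene pair c.833T>C /
c.844_845ins68: a 68 bp tandem-duplication insertion (the last 52 bases of
intron 7 plus the first 16 bases of exon 8) whose phase with the SNV decides
pathogenicity.  This module builds a *synthetic* 5000 bp stand-in sequence
that reproduces the coordinate structure of that locus exactly while carrying
randomly generated flanking sequence:

* duplicated segment at WT 3173–3240 (68 bp), copy inserted before 3173;
* SNV at WT 3184 (A>G, the plus-strand image of c.833T>C), whose cis image
  falls at MU 3252 = 3184 + 68;
* engineered marker at insertion offset 38 → MU 3210, natural base G,
  scaffold base C (the MU:3210C>G "predetermined variant call");
* genomic anchor chr21:44,480,001 so WT 3184 maps to chr21:44,483,184.

The common insertion allele diverges from the duplicated segment at 3 offsets,
the rare allele at 4; offsets are configurable through
:class:`~scaffoldcall.reference_model.InsertionSpec` so real allele sequences
can be substituted.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .reference_model import (
    InsertionSpec,
    MarkerSpec,
    ReferenceRegion,
    ScaffoldSet,
    SnvSpec,
    build_scaffolds,
)

__all__ = [
    "cbs_synthetic_reference",
    "common_insertion",
    "rare_insertion",
    "cbs_marker",
    "cbs_snv",
    "cbs_synthetic_scaffolds",
]

# fixed internal seed: the fixture is a deterministic synthetic sequence, not a dial
_FIXTURE_SEED = 21_844_068

SOURCE_START = 3173
SOURCE_END = 3240
INSERTION_POINT = 3173
SNV_POSITION = 3184
MARKER_OFFSET = 38
COMMON_DIVERGENT_OFFSETS = (5, 30, 60)
RARE_DIVERGENT_OFFSETS = (5, 30, 45, 60)

# deterministic divergent substitution (transversion-like, never identity)
_DIVERGE = {"A": "C", "C": "A", "G": "T", "T": "G"}


@lru_cache(maxsize=None)
def cbs_synthetic_reference(length: int = 5000) -> ReferenceRegion:
    """The synthetic 5000 bp CBS-analog reference region (anchored to
    chr21:44,480,001 so local coordinates mirror the real locus)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, size=length)))
    seq[SNV_POSITION - 1] = "A"  # SNV reference base (A>G)
    seq[SOURCE_START + MARKER_OFFSET - 2] = "G"  # natural marker base at WT 3210
    return ReferenceRegion(
        name="CBSsyn", sequence="".join(seq), chrom="chr21", anchor_start=44_480_001
    )


def _insertion(offsets: tuple[int, ...], label: str) -> InsertionSpec:
    ref = cbs_synthetic_reference()
    segment = ref.sequence[SOURCE_START - 1 : SOURCE_END]
    divergent = tuple((off, _DIVERGE[segment[off - 1]]) for off in offsets)
    return InsertionSpec(
        source_start=SOURCE_START,
        source_end=SOURCE_END,
        insertion_point=INSERTION_POINT,
        divergent_bases=divergent,
        allele_label=label,
    )


def common_insertion() -> InsertionSpec:
    """The common insertion allele: 3 divergent bases (~96% identical)."""
    return _insertion(COMMON_DIVERGENT_OFFSETS, "common")


def rare_insertion() -> InsertionSpec:
    """The rare insertion allele: one additional divergent base (~94% identical)."""
    return _insertion(RARE_DIVERGENT_OFFSETS, "rare")


def cbs_marker() -> MarkerSpec:
    return MarkerSpec(insertion_offset=MARKER_OFFSET, scaffold_base="C", natural_base="G")


def cbs_snv() -> SnvSpec:
    return SnvSpec(wt_position=SNV_POSITION, ref_base="A", alt_base="G")


@lru_cache(maxsize=None)
def cbs_synthetic_scaffolds() -> ScaffoldSet:
    """The CBS-analog scaffold pair (WT 5000 bp, MU 5068 bp; sites
    3184 / 3210 / 3252)."""
    return build_scaffolds(
        cbs_synthetic_reference(), common_insertion(), cbs_marker(), cbs_snv()
    )
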