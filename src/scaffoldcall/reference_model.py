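"""Construction of wild-type / mutant scaffold pairs for targeted complex variants.

A *scaffold* is a supplementary reference sequence tailored to one haplotype of
a complex structural variant.  For a tandem-duplication insertion the pair
consists of

* a wild-type scaffold (``*_WT``) — the unmodified reference region, and
* a mutant scaffold (``*_MU``) — the same region carrying the inserted copy of
  the duplicated segment, with the insertion's divergent bases applied and one
  additional engineered *marker* base written inside the copy.

The marker is a deliberate mismatch at a conserved position: every read that
truly carries the insertion reports the natural allele against the engineered
scaffold base, producing a predetermined "variant" call that cleanly tags
insertion-bearing reads.  All coordinates are 1-based, closed intervals, on the
plus strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceRegion",
    "InsertionSpec",
    "MarkerSpec",
    "SnvSpec",
    "Site",
    "ScaffoldSet",
    "build_scaffolds",
    "lift_coordinate",
    "equivalent_insertion_descriptions",
    "write_scaffolds",
    "read_scaffolds",
]

_DNA = frozenset("ACGT")


def _check_dna(seq: str) -> None:
    if not seq:
        raise ValueError("sequence must be non-empty")
    if not _DNA.issuperset(seq):
        bad = sorted(set(seq) - _DNA)
        raise ValueError(f"sequence restricted to A/C/G/T uppercase; found {bad}")


@dataclass(frozen=True)
class ReferenceRegion:
    """A named reference sequence, optionally anchored to genome coordinates.

    With an anchor (``chrom``, ``anchor_start``), local 1-based position *p*
    maps to genome position ``anchor_start + p - 1``.
    """

    name: str
    sequence: str
    chrom: str | None = None
    anchor_start: int | None = None

    def __post_init__(self) -> None:
        _check_dna(self.sequence)
        if (self.chrom is None) != (self.anchor_start is None):
            raise ValueError("genomic anchor needs both chrom and anchor_start")

    def __len__(self) -> int:
        return len(self.sequence)

    def genome_position(self, pos: int) -> int:
        """Map local 1-based position to the anchored genome coordinate."""
        if self.anchor_start is None:
            raise ValueError(f"{self.name} has no genomic anchor")
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(f"position {pos} outside {self.name}")
        return self.anchor_start + pos - 1


@dataclass(frozen=True)
class InsertionSpec:
    """A tandem-duplication insertion: a copy of ``[source_start, source_end]``
    inserted immediately before ``insertion_point``, with ``divergent_bases``
    (1-based offset within the copy → replacement base) applied to the copy."""

    source_start: int
    source_end: int
    insertion_point: int
    divergent_bases: tuple[tuple[int, str], ...] = ()
    allele_label: str = "common"

    def __post_init__(self) -> None:
        if self.source_start < 1 or self.source_end < self.source_start:
            raise ValueError("invalid source interval")
        offs = [o for o, _ in self.divergent_bases]
        if len(offs) != len(set(offs)):
            raise ValueError("duplicate divergent offsets")
        for off, base in self.divergent_bases:
            if not 1 <= off <= self.length:
                raise ValueError(f"divergent offset {off} outside insertion")
            if base not in _DNA:
                raise ValueError(f"invalid divergent base {base!r}")

    @property
    def length(self) -> int:
        return self.source_end - self.source_start + 1


@dataclass(frozen=True)
class MarkerSpec:
    """The engineered marker base inside the inserted copy.

    ``scaffold_base`` is written into the mutant scaffold; ``natural_base`` is
    what real insertion alleles carry at that offset, so every genuine
    insertion read produces an expected mismatch at the marker."""

    insertion_offset: int
    scaffold_base: str
    natural_base: str

    def __post_init__(self) -> None:
        if self.scaffold_base not in _DNA or self.natural_base not in _DNA:
            raise ValueError("marker bases must be A/C/G/T")
        if self.scaffold_base == self.natural_base:
            raise ValueError(
                "marker scaffold base equals the natural base; no expected "
                "mismatch is possible"
            )


@dataclass(frozen=True)
class SnvSpec:
    """The single-nucleotide variant phased against the insertion."""

    wt_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise ValueError("SNV bases must be A/C/G/T")
        if self.ref_base == self.alt_base:
            raise ValueError("SNV ref and alt bases must differ")


@dataclass(frozen=True)
class Site:
    """An informative site: one scaffold position whose pileup allele fraction
    feeds the genotype decision table."""

    name: str
    scaffold: str  # "wt" | "mu"
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ScaffoldSet:
    """The WT/MU scaffold pair with its informative-site manifest."""

    wt: ReferenceRegion
    mu: ReferenceRegion
    insertion: InsertionSpec
    marker: MarkerSpec
    snv: SnvSpec
    sites: dict[str, int] = field(compare=False)

    @property
    def insertion_length(self) -> int:
        return self.insertion.length

    def natural_insert(self) -> str:
        """The inserted copy as carried by real molecules (divergent bases
        applied, natural base at the marker offset)."""
        ins = self.insertion
        copy = list(self.wt.sequence[ins.source_start - 1 : ins.source_end])
        for off, base in ins.divergent_bases:
            copy[off - 1] = base
        return "".join(copy)

    def scaffold_insert(self) -> str:
        """The inserted copy as written into the MU scaffold (marker applied)."""
        copy = list(self.natural_insert())
        copy[self.marker.insertion_offset - 1] = self.marker.scaffold_base
        return "".join(copy)

    def informative_sites(self) -> tuple[Site, Site, Site]:
        """The three informative sites.  The designated alt allele is the SNV
        alt base at the SNV sites and the natural base at the marker."""
        return (
            Site("wt_snv", "wt", self.sites["wt_snv"], self.snv.ref_base, self.snv.alt_base),
            Site("mu_marker", "mu", self.sites["mu_marker"], self.marker.scaffold_base,
                 self.marker.natural_base),
            Site("mu_cis_snv", "mu", self.sites["mu_cis_snv"], self.snv.ref_base,
                 self.snv.alt_base),
        )


def build_scaffolds(
    ref: ReferenceRegion,
    ins: InsertionSpec,
    marker: MarkerSpec,
    snv: SnvSpec,
) -> ScaffoldSet:
    """Build the WT/MU scaffold pair for one insertion + SNV specification.

    The WT scaffold is ``ref`` unchanged.  The MU scaffold is
    ``ref[1..insertion_point-1] + copy + ref[insertion_point..]`` where ``copy``
    is the source segment with divergent bases applied and then the marker
    scaffold base written at the marker offset.  Placing the modified copy
    *first* (upstream of the retained original segment) is what puts the cis
    image of the SNV downstream of the insertion at ``wt_position +
    insertion_length`` and keeps the marker inside the inserted copy.
    """
    n = len(ref)
    if ins.source_end > n:
        raise ValueError("source interval outside the reference region")
    if not 1 <= ins.insertion_point <= n + 1:
        raise ValueError("insertion point outside the reference region")
    if ins.insertion_point not in (ins.source_start, ins.source_end + 1):
        raise ValueError(
            "insertion point must be tandem with the source interval "
            "(immediately before its start or after its end)"
        )
    if not 1 <= marker.insertion_offset <= ins.length:
        raise ValueError("marker offset outside the inserted copy")
    if any(off == marker.insertion_offset for off, _ in ins.divergent_bases):
        raise ValueError("divergent offset collides with the marker offset")
    if not 1 <= snv.wt_position <= n:
        raise ValueError("SNV position outside the reference region")
    if ref.sequence[snv.wt_position - 1] != snv.ref_base:
        raise ValueError(
            f"SNV ref base {snv.ref_base} does not match reference "
            f"{ref.sequence[snv.wt_position - 1]} at {snv.wt_position}"
        )

    segment = ref.sequence[ins.source_start - 1 : ins.source_end]
    copied_at_marker = segment[marker.insertion_offset - 1]
    # divergent bases must actually diverge, and the marker must be engineered
    # relative to the base the copy truly carries there
    for off, base in ins.divergent_bases:
        if segment[off - 1] == base:
            raise ValueError(f"divergent base at offset {off} equals the copied base")
    if marker.natural_base != copied_at_marker:
        raise ValueError(
            f"marker natural base {marker.natural_base} does not match the "
            f"copied base {copied_at_marker} at insertion offset "
            f"{marker.insertion_offset}"
        )
    if marker.scaffold_base == copied_at_marker:
        raise ValueError("marker scaffold base equals the natural copied base")

    copy = list(segment)
    for off, base in ins.divergent_bases:
        copy[off - 1] = base
    copy[marker.insertion_offset - 1] = marker.scaffold_base
    ip = ins.insertion_point
    mu_seq = ref.sequence[: ip - 1] + "".join(copy) + ref.sequence[ip - 1 :]

    wt = ReferenceRegion(f"{ref.name}_WT", ref.sequence, ref.chrom, ref.anchor_start)
    mu = ReferenceRegion(f"{ref.name}_MU", mu_seq)
    sites = {
        "wt_snv": snv.wt_position,
        "mu_marker": ip - 1 + marker.insertion_offset,
        "mu_cis_snv": snv.wt_position + ins.length if snv.wt_position >= ip
        else snv.wt_position,
    }
    return ScaffoldSet(wt=wt, mu=mu, insertion=ins, marker=marker, snv=snv, sites=sites)


def lift_coordinate(s: ScaffoldSet, frm: str, pos: int) -> int | None:
    """Lift a position between the WT and MU scaffolds.

    WT→MU: positions upstream of the insertion point map to themselves,
    positions at/downstream map shifted by the insertion length.  MU→WT is the
    inverse; MU positions inside the inserted copy have no WT image and return
    ``None``.
    """
    ip = s.insertion.insertion_point
    ln = s.insertion_length
    if frm == "wt":
        if not 1 <= pos <= len(s.wt):
            raise ValueError(f"position {pos} outside WT scaffold")
        return pos if pos < ip else pos + ln
    if frm == "mu":
        if not 1 <= pos <= len(s.mu):
            raise ValueError(f"position {pos} outside MU scaffold")
        if pos < ip:
            return pos
        if pos < ip + ln:
            return None  # inside the inserted copy
        return pos - ln
    raise ValueError("frm must be 'wt' or 'mu'")


def _apply_insertion(ref: str, pos: int, ins: str) -> str:
    return ref[: pos - 1] + ins + ref[pos - 1 :]


def equivalent_insertion_descriptions(
    ref: str,
    desc_a: tuple[int, str],
    desc_b: tuple[int, str],
) -> bool:
    """Whether two (position, inserted-string) descriptions denote the same
    allele.

    Insertions in repeated context admit shifted but equivalent descriptions;
    two descriptions are the same allele iff applying each to the reference
    yields the identical sequence.
    """
    _check_dna(ref)
    for pos, ins in (desc_a, desc_b):
        if not ins:
            raise ValueError("empty insertion string")
        _check_dna(ins)
        if not 1 <= pos <= len(ref) + 1:
            raise ValueError(f"insertion position {pos} outside the reference")
    return _apply_insertion(ref, *desc_a) == _apply_insertion(ref, *desc_b)


_MANIFEST = "sites.yaml"


def write_scaffolds(s: ScaffoldSet, out_dir: str) -> dict[str, str]:
    """Write the scaffold pair as a 2-record FASTA plus a sites manifest.

    Returns the paths written.  Round-trips through :func:`read_scaffolds`.
    """
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "scaffolds.fasta")
    try:
        records = [
            SeqRecord(Seq(s.wt.sequence), id=s.wt.name, description=""),
            SeqRecord(Seq(s.mu.sequence), id=s.mu.name, description=""),
        ]
        SeqIO.write(records, fasta, "fasta")  # Biopython wraps at 60 columns
    except OSError as exc:
        raise OSError(f"cannot write scaffold FASTA to {fasta}: {exc}") from exc

    sites = s.informative_sites()
    manifest = {
        "wt_name": s.wt.name,
        "mu_name": s.mu.name,
        "anchor": None
        if s.wt.chrom is None
        else {"chrom": s.wt.chrom, "start": s.wt.anchor_start},
        "insertion": {
            "source_start": s.insertion.source_start,
            "source_end": s.insertion.source_end,
            "insertion_point": s.insertion.insertion_point,
            "divergent_bases": [[o, b] for o, b in s.insertion.divergent_bases],
            "allele_label": s.insertion.allele_label,
        },
        "marker": {
            "insertion_offset": s.marker.insertion_offset,
            "scaffold_base": s.marker.scaffold_base,
            "natural_base": s.marker.natural_base,
        },
        "snv": {
            "wt_position": s.snv.wt_position,
            "ref_base": s.snv.ref_base,
            "alt_base": s.snv.alt_base,
        },
        "sites": [
            {"name": t.name, "scaffold": t.scaffold, "pos": t.pos,
             "ref": t.ref, "alt": t.alt}
            for t in sites
        ],
    }
    manifest_path = os.path.join(out_dir, _MANIFEST)
    try:
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    except OSError as exc:
        raise OSError(f"cannot write sites manifest to {manifest_path}: {exc}") from exc
    return {"fasta": fasta, "manifest": manifest_path}


def read_scaffolds(in_dir: str) -> ScaffoldSet:
    """Rebuild a :class:`ScaffoldSet` from :func:`write_scaffolds` output."""
    fasta = os.path.join(in_dir, "scaffolds.fasta")
    manifest_path = os.path.join(in_dir, _MANIFEST)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta, "fasta")}
    anchor = man.get("anchor") or {}
    base_name = man["wt_name"]
    if base_name.endswith("_WT"):
        base_name = base_name[:-3]
    ref = ReferenceRegion(
        base_name,
        seqs[man["wt_name"]],
        anchor.get("chrom"),
        anchor.get("start"),
    )
    ins = InsertionSpec(
        source_start=man["insertion"]["source_start"],
        source_end=man["insertion"]["source_end"],
        insertion_point=man["insertion"]["insertion_point"],
        divergent_bases=tuple((o, b) for o, b in man["insertion"]["divergent_bases"]),
        allele_label=man["insertion"]["allele_label"],
    )
    marker = MarkerSpec(**man["marker"])
    snv = SnvSpec(**man["snv"])
    s = build_scaffolds(ref, ins, marker, snv)
    if s.mu.sequence != seqs[man["mu_name"]]:
        raise ValueError("MU scaffold FASTA does not match the manifest specification")
    return s
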