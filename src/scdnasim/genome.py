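"""Build per-cell diploid mutated genomes and verify them.

Each cell's genome is represented as two explicit haplotypes (A and B).
HOM variants are applied to both, HET variants to one haplotype chosen by a
fair coin.  Substitutions keep coordinates fixed; insertions add their
sequence immediately after the 1-based anchor base; deletions remove the
anchor base and the following ``length - 1`` bases.  A per-haplotype
:class:`CoordMap` translates reference coordinates to haplotype coordinates
(undefined inside deletions).

Copy number is deliberately *not* materialised in these sequences: depth is
realised at read-sampling time, which keeps coordinates stable and makes
the point-variant round trip exactly verifiable.

:func:`generating_accuracy` re-derives each variant's placement from the
sequences alone (phase is inferred, never read from the builder), so the
round-trip check is independent of the construction path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .refio import ReferenceGenome, write_fasta
from .snp import SNPRecord
from .snv_indel import IndelRecord, SNVRecord

__all__ = [
    "VariantCall",
    "CoordMap",
    "HaplotypeGenome",
    "as_calls",
    "build_cell_genome",
    "generating_accuracy",
    "write_cell_fastas",
]


class VariantCall(NamedTuple):
    """Normalised variant: SUB (SNP/SNV), INS, or DEL."""

    chrom: str
    pos: int  # 1-based; SUB/INS anchor or first deleted base
    kind: str  # "SUB" | "INS" | "DEL"
    ref: str  # SUB only
    alt: str  # SUB only
    length: int  # indels only (0 for SUB)
    seq: str  # INS only
    genotype: str  # "HET" | "HOM"


def as_calls(records: Iterable) -> list[VariantCall]:
    """Normalise SNP/SNV/indel records into VariantCalls."""
    calls = []
    for r in records:
        if isinstance(r, (SNPRecord, SNVRecord)):
            calls.append(
                VariantCall(r.chrom, r.pos, "SUB", r.ref, r.alt, 0, "", r.genotype)
            )
        elif isinstance(r, IndelRecord):
            calls.append(
                VariantCall(r.chrom, r.pos, r.kind, "", "", r.length, r.seq, r.genotype)
            )
        elif isinstance(r, VariantCall):
            calls.append(r)
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
    return calls


class CoordMap:
    """Monotone reference -> haplotype coordinate map (1-based both sides)."""

    def __init__(self, ref_len: int, events: list[tuple[int, str, int]] = ()):
        """``events``: ascending (pos, kind, length) for applied indels."""
        self.ref_len = ref_len
        anchors = [1]
        offsets = [0]
        del_starts: list[int] = []
        del_ends: list[int] = []
        cum = 0
        for pos, kind, length in events:
            if kind == "INS":
                cum += length
                anchors.append(pos + 1)
                offsets.append(cum)
            elif kind == "DEL":
                del_starts.append(pos)
                del_ends.append(pos + length - 1)
                cum -= length
                anchors.append(pos + length)
                offsets.append(cum)
            else:
                raise ValueError(f"unknown coord event kind {kind!r}")
        self._anchors = np.array(anchors)
        self._offsets = np.array(offsets)
        self._del_starts = np.array(del_starts)
        self._del_ends = np.array(del_ends)
        self.hap_len = ref_len + cum

    def is_deleted(self, pos: int) -> bool:
        i = int(np.searchsorted(self._del_starts, pos, side="right")) - 1
        return i >= 0 and pos <= int(self._del_ends[i])

    def map(self, pos: int) -> int | None:
        """Haplotype position of reference ``pos``; None inside deletions."""
        if not 1 <= pos <= self.ref_len:
            raise ValueError(f"reference position {pos} out of range")
        if self.is_deleted(pos):
            return None
        i = int(np.searchsorted(self._anchors, pos, side="right")) - 1
        return pos + int(self._offsets[i])

    def first_defined_at_or_after(self, pos: int) -> int | None:
        if self.is_deleted(pos):
            i = int(np.searchsorted(self._del_starts, pos, side="right")) - 1
            pos = int(self._del_ends[i]) + 1
        return pos if pos <= self.ref_len else None

    def last_defined_at_or_before(self, pos: int) -> int | None:
        if self.is_deleted(pos):
            i = int(np.searchsorted(self._del_starts, pos, side="right")) - 1
            pos = int(self._del_starts[i]) - 1
        return pos if pos >= 1 else None

    def map_range(self, start: int, end: int) -> tuple[int, int] | None:
        """Haplotype extent covering reference [start, end]; None if empty."""
        rs = self.first_defined_at_or_after(start)
        re_ = self.last_defined_at_or_before(end)
        if rs is None or re_ is None or rs > re_:
            return None
        return self.map(rs), self.map(re_)


@dataclass
class HaplotypeGenome:
    """The two mutated haplotypes of one cell, with coordinate maps."""

    cell_id: str
    haplotypes: dict[str, dict[str, str]]  # hap ("A"/"B") -> contig -> seq
    coord_maps: dict[tuple[str, str], CoordMap]  # (hap, contig) -> map
    phase: dict[tuple[str, int], str] = field(default_factory=dict)

    @classmethod
    def from_reference(cls, genome: ReferenceGenome, cell_id: str) -> "HaplotypeGenome":
        """Identity genome (no point variants), e.g. for CNV-only cells."""
        maps = {}
        for hap in "AB":
            for name, seq in genome.contigs.items():
                maps[(hap, name)] = CoordMap(len(seq))
        return cls(
            cell_id=cell_id,
            haplotypes={"A": dict(genome.contigs), "B": dict(genome.contigs)},
            coord_maps=maps,
        )


def build_cell_genome(
    genome: ReferenceGenome,
    snps: Iterable = (),
    snvs: Iterable = (),
    indels: Iterable = (),
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
) -> HaplotypeGenome:
    """Apply one cell's variants to the reference, yielding two haplotypes.

    HOM variants hit both haplotypes; each HET variant lands on haplotype A
    or B by a fair coin (one draw per variant, in genome order).  Requires
    pairwise-disjoint variant intervals (guaranteed by the simulators).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    calls = as_calls(list(snps) + list(snvs) + list(indels))
    order = {name: i for i, name in enumerate(genome.contigs)}
    for c in calls:
        if c.chrom not in order:
            raise ValueError(f"variant on unknown contig {c.chrom!r}")
    calls.sort(key=lambda c: (order[c.chrom], c.pos))

    # one coin per HET variant, drawn in genome order
    target: list[str] = []
    for c in calls:
        if c.genotype == "HOM":
            target.append("AB")
        else:
            target.append("A" if rng.random() < 0.5 else "B")

    haplotypes: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    coord_maps: dict[tuple[str, str], CoordMap] = {}
    phase = {(c.chrom, c.pos): t for c, t in zip(calls, target)}

    for name, ref_seq in genome.contigs.items():
        contig_calls = [
            (c, t) for c, t in zip(calls, target) if c.chrom == name
        ]
        # overlap sanity check: consumed reference intervals must be disjoint
        prev_end = 0
        for c, _ in contig_calls:
            span = c.length if c.kind == "DEL" else 1
            if c.pos <= prev_end:
                raise ValueError(
                    f"overlapping variants on {name} at position {c.pos}"
                )
            if c.pos + span - 1 > len(ref_seq):
                raise ValueError(
                    f"variant at {name}:{c.pos} extends beyond the contig"
                )
            if c.kind == "SUB" and ref_seq[c.pos - 1] != c.ref:
                raise ValueError(
                    f"SUB at {name}:{c.pos}: profile ref {c.ref!r} does not "
                    f"match reference base {ref_seq[c.pos - 1]!r}"
                )
            prev_end = c.pos + span - 1
        for hap in "AB":
            pieces = []
            events = []
            prev = 1  # next reference position to copy, 1-based
            for c, t in contig_calls:
                if hap not in t:
                    continue
                if c.kind == "SUB":
                    pieces.append(ref_seq[prev - 1 : c.pos - 1])
                    pieces.append(c.alt)
                    prev = c.pos + 1
                elif c.kind == "INS":
                    pieces.append(ref_seq[prev - 1 : c.pos])
                    pieces.append(c.seq)
                    prev = c.pos + 1
                    events.append((c.pos, "INS", c.length))
                else:  # DEL
                    pieces.append(ref_seq[prev - 1 : c.pos - 1])
                    prev = c.pos + c.length
                    events.append((c.pos, "DEL", c.length))
            pieces.append(ref_seq[prev - 1 :])
            haplotypes[hap][name] = "".join(pieces)
            coord_maps[(hap, name)] = CoordMap(len(ref_seq), events)

    return HaplotypeGenome(
        cell_id=cell_id, haplotypes=haplotypes, coord_maps=coord_maps, phase=phase
    )


_VERIFY_EXT = 10  # matches the indel placement buffer


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def _hamming_to_plain(seq: str, i: int, want_plain: str) -> int:
    return _hamming(seq[i : i + len(want_plain)], want_plain)


def generating_accuracy(
    genome: ReferenceGenome,
    records: Iterable,
    hap_a: dict[str, str],
    hap_b: dict[str, str],
) -> float:
    """Fraction of ground-truth variants verifiably present in the haplotypes.

    Works from sequences alone: per contig, variants are checked in
    ascending order while per-haplotype indel offsets are accumulated; HET
    phase is inferred from which haplotype carries the expected content.  A
    HOM variant verifies iff both haplotypes carry it; a HET variant iff
    exactly one assignment (carrier + reference-like partner) matches
    exactly.  Returns 1.0 for an empty profile.
    """
    calls = as_calls(records)
    if not calls:
        return 1.0
    order = {name: i for i, name in enumerate(genome.contigs)}
    calls.sort(key=lambda c: (order.get(c.chrom, len(order)), c.pos))

    verified = 0
    current = None
    for call in calls:
        if call.chrom != current:
            current = call.chrom
            ref = genome.contigs[current]
            ha = hap_a.get(current, "")
            hb = hap_b.get(current, "")
            off = {"A": 0, "B": 0}
        pos = call.pos
        if call.kind == "SUB":
            ok = {}
            is_ref = {}
            for hap, seq in (("A", ha), ("B", hb)):
                i = pos + off[hap] - 1
                base = seq[i] if 0 <= i < len(seq) else ""
                ok[hap] = base == call.alt
                is_ref[hap] = base == call.ref
            if call.genotype == "HOM":
                verified += ok["A"] and ok["B"]
            else:
                verified += (ok["A"] and not ok["B"] and is_ref["B"]) or (
                    ok["B"] and not ok["A"] and is_ref["A"]
                )
        else:  # INS or DEL
            # Compare against windows extended by up to EXT reference bases
            # past the event: a tandem repeat as long as the event itself
            # would otherwise make "applied" and "not applied" identical
            # (e.g. deleting one copy of a duplicated 4-mer).  The indel
            # placement buffer guarantees those EXT bases are unedited.
            l = call.length
            if call.kind == "INS":
                w = min(_VERIFY_EXT, len(ref) - pos)
                cont = ref[pos : pos + w]  # continuation after the anchor
                want_carrier = call.seq + cont
                want_plain = cont
                shift = l
                i0 = pos  # 0-based index just past the anchor
            else:  # DEL
                w = min(_VERIFY_EXT, len(ref) - (pos + l - 1))
                want_carrier = ref[pos + l - 1 : pos + l - 1 + w]
                want_plain = ref[pos - 1 : pos - 1 + l + w]
                shift = -l
                i0 = pos - 1  # 0-based index of the first deleted base
            carrier_exact = {}
            plain_exact = {}
            mism = {}
            for hap, seq in (("A", ha), ("B", hb)):
                i = i0 + off[hap]
                region_c = seq[i : i + len(want_carrier)]
                region_p = seq[i : i + len(want_plain)]
                if call.kind == "DEL" and w == 0:
                    # deletion at the contig end: only length evidence
                    carrier_exact[hap] = len(seq) == i
                    mism[hap] = 0 if carrier_exact[hap] else len(want_plain)
                else:
                    carrier_exact[hap] = region_c == want_carrier
                    mism[hap] = _hamming(region_c, want_carrier)
                plain_exact[hap] = region_p == want_plain
            if call.genotype == "HOM":
                verified += carrier_exact["A"] and carrier_exact["B"]
                carriers = {
                    hap: carrier_exact[hap]
                    or mism[hap] < _hamming_to_plain(ha if hap == "A" else hb,
                                                     i0 + off[hap], want_plain)
                    for hap in "AB"
                }
            else:
                a_case = carrier_exact["A"] and plain_exact["B"]
                b_case = carrier_exact["B"] and plain_exact["A"]
                verified += a_case or b_case
                if a_case and not b_case:
                    carriers = {"A": True, "B": False}
                elif b_case and not a_case:
                    carriers = {"A": False, "B": True}
                else:
                    pick = "A" if mism["A"] <= mism["B"] else "B"
                    carriers = {"A": pick == "A", "B": pick == "B"}
            for hap in "AB":
                if carriers[hap]:
                    off[hap] += shift
    return verified / len(calls)


def write_cell_fastas(hap: HaplotypeGenome, out_dir, line_width: int = 60) -> list[Path]:
    """Write the two haplotype FASTAs of one cell (suffix _hapA/_hapB)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for h in "AB":
        path = out_dir / f"{hap.cell_id}_hap{h}.fa"
        write_fasta(ReferenceGenome(hap.haplotypes[h]), path, line_width=line_width)
        paths.append(path)
    return paths
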