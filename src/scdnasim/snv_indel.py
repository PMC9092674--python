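"""De novo SNV and short-indel simulation from the reference sequence.

SNVs are drawn per cell at distinct uniform non-N positions (fully private
to each cell — no sharing rule applies outside SNPs).  Indels are 4-10 bp
insertions or deletions, placed by rejection sampling so that within a cell
every indel keeps a 10 bp buffer from all other variants; this guarantees
unambiguous genome building and exact round-trip verification.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from ._rng import child_rng
from .params import SimulationParams
from .refio import ReferenceGenome

__all__ = [
    "SNVRecord",
    "IndelRecord",
    "simulate_snv_profiles",
    "simulate_indel_profiles",
    "write_snv_profiles",
    "write_indel_profiles",
]

MIN_INDEL_LEN = 4
MAX_INDEL_LEN = 10
BUFFER = 10  # bp of exclusion on each side of a variant

_BASES = "ACGT"
_B_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class SNVRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str


class IndelRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based anchor; for DEL, the first deleted base
    kind: str  # "INS" or "DEL"
    length: int  # in [4, 10]
    seq: str  # inserted bases for INS, "" for DEL
    genotype: str


def _contig_arrays(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    return {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for name, seq in genome.contigs.items()
    }


def simulate_snv_profiles(
    params: SimulationParams, genome: ReferenceGenome
) -> list[list[SNVRecord]]:
    """Per cell, ``snv_no`` distinct uniform non-N sites, sampled independently.

    alt is uniform over the three non-reference bases; genotype is HET with
    probability ``het_rate``.  Deterministic per seed.
    """
    arrays = _contig_arrays(genome)
    names = list(arrays)
    valid = {n: np.nonzero(arrays[n] != ord("N"))[0] for n in names}
    counts = np.array([len(valid[n]) for n in names])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(counts.sum())
    if params.snv_no > total:
        raise ValueError(
            f"snv_no={params.snv_no} exceeds {total} non-N reference positions"
        )
    out: list[list[SNVRecord]] = []
    order = {n: i for i, n in enumerate(names)}
    for c in range(params.cell_no):
        rng = child_rng(params.seed, "snv", c)
        flat = rng.choice(total, size=params.snv_no, replace=False)
        shifts = rng.integers(1, 4, size=params.snv_no)
        hets = rng.random(params.snv_no) < params.het_rate
        records = []
        for f, shift, het in zip(flat, shifts, hets):
            ci = int(np.searchsorted(offsets, f, side="right")) - 1
            name = names[ci]
            pos0 = int(valid[name][f - offsets[ci]])
            ref = chr(arrays[name][pos0])
            ref_idx = _BASES.index(ref)
            alt = _BASES[(ref_idx + int(shift)) % 4]
            records.append(
                SNVRecord(name, pos0 + 1, ref, alt, "HET" if het else "HOM")
            )
        records.sort(key=lambda r: (order[r.chrom], r.pos))
        out.append(records)
    return out


def simulate_indel_profiles(
    params: SimulationParams,
    genome: ReferenceGenome,
    exclude: list[Iterable[tuple[str, int]]] | None = None,
) -> list[list[IndelRecord]]:
    """Per cell, ``indel_no`` non-overlapping 4-10 bp insertions/deletions.

    Kind is INS/DEL with probability 1/2 each, length uniform on {4..10},
    inserted bases i.i.d. uniform ACGT.  Anchors are rejection-sampled so
    the protected interval of every indel (the event span padded by 10 bp
    on each side) avoids all other variants in the same cell, including the
    optional ``exclude`` point-variant positions.  Deterministic per seed.
    """
    arrays = _contig_arrays(genome)
    names = list(arrays)
    lengths = {n: len(arrays[n]) for n in names}
    counts = np.array([lengths[n] for n in names])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(counts.sum())
    order = {n: i for i, n in enumerate(names)}
    out: list[list[IndelRecord]] = []
    for c in range(params.cell_no):
        rng = child_rng(params.seed, "indel", c)
        # blocked[p] marks 1-based reference positions an indel must avoid
        blocked = {n: np.zeros(lengths[n] + 2, dtype=bool) for n in names}
        if exclude is not None and c < len(exclude):
            for chrom, pos in exclude[c]:
                lo = max(1, pos - BUFFER)
                hi = min(lengths[chrom], pos + BUFFER)
                blocked[chrom][lo : hi + 1] = True
        records: list[IndelRecord] = []
        tries = 0
        max_tries = 200 * max(params.indel_no, 1) + 200
        while len(records) < params.indel_no:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"cell {c}: could not place {params.indel_no} "
                    f"non-overlapping indels after {max_tries} attempts"
                )
            f = int(rng.integers(total))
            ci = int(np.searchsorted(offsets, f, side="right")) - 1
            name = names[ci]
            pos = f - int(offsets[ci]) + 1  # 1-based anchor
            is_ins = rng.random() < 0.5
            length = int(rng.integers(MIN_INDEL_LEN, MAX_INDEL_LEN + 1))
            span = 1 if is_ins else length  # reference bases consumed
            if pos + span - 1 > lengths[name]:
                continue
            region = arrays[name][pos - 1 : pos + span - 1]
            if (region == ord("N")).any():
                continue
            lo = max(1, pos - BUFFER)
            hi = min(lengths[name], pos + span - 1 + BUFFER)
            if blocked[name][lo : hi + 1].any():
                continue
            blocked[name][lo : hi + 1] = True
            seq = ""
            if is_ins:
                seq = _B_ARR[rng.integers(0, 4, size=length)].tobytes().decode()
            gt = "HET" if rng.random() < params.het_rate else "HOM"
            records.append(
                IndelRecord(name, pos, "INS" if is_ins else "DEL", length, seq, gt)
            )
        records.sort(key=lambda r: (order[r.chrom], r.pos))
        out.append(records)
    return out


def _write_profiles(profiles, out_dir, suffix, header, fmt) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, records in enumerate(profiles):
        cell_id = f"cell{c}"
        path = out_dir / f"{cell_id}.{suffix}.tsv"
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(header)
            for r in records:
                fh.write(fmt(cell_id, r))
        paths.append(path)
    return paths


def write_snv_profiles(profiles: list[list[SNVRecord]], out_dir) -> list[Path]:
    return _write_profiles(
        profiles, out_dir, "snv",
        "cell_id\tchrom\tpos\tref\talt\tgenotype\n",
        lambda cid, r: f"{cid}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.genotype}\n",
    )


def write_indel_profiles(profiles: list[list[IndelRecord]], out_dir) -> list[Path]:
    return _write_profiles(
        profiles, out_dir, "indel",
        "cell_id\tchrom\tpos\tkind\tlength\tseq\tgenotype\n",
        lambda cid, r: (
            f"{cid}\t{r.chrom}\t{r.pos}\t{r.kind}\t{r.length}\t{r.seq}\t{r.genotype}\n"
        ),
    )
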