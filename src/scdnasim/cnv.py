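"""Copy-number ground truth: bins, segments, subclones, noise, and writers.

The CNV model is a cells x bins integer matrix.  Each contig is tiled with
``bin_len``-wide bins (last bin possibly shorter) and split into ``seg_no``
segments by ``seg_no - 1`` interior bin boundaries drawn uniformly without
replacement.  Cells are either normal (all bins CN=2) or belong to one of
``cluster_no`` tumor clones; a clone's profile assigns one copy number per
segment (neutral CN=2 with probability ``p_neutral``, otherwise uniform over
{0,1} U {3..max_cn}), with every clone guaranteed at least one aberrant
segment and all clone profiles pairwise distinct.  Noise perturbs each
matrix entry independently by +/-1 with probability ``noise_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import round_half_away

__all__ = [
    "GenomicBin",
    "BinSet",
    "SegmentSet",
    "CNVMatrix",
    "make_bins",
    "draw_segments",
    "assign_clusters",
    "draw_clone_profiles",
    "build_matrix",
    "inject_noise",
    "write_cnv_outputs",
]


class GenomicBin(NamedTuple):
    chrom: str
    start: int  # 1-based
    end: int  # inclusive


@dataclass
class BinSet:
    """Fixed-width tiling of every contig; bins in contig order."""

    bins: list[GenomicBin]
    contig_lengths: dict[str, int]
    bin_len: int

    @classmethod
    def from_lengths(cls, lengths: dict[str, int], bin_len: int) -> "BinSet":
        if bin_len < 1:
            raise ValueError("bin_len must be >= 1")
        bins = []
        for chrom, clen in lengths.items():
            start = 1
            while start <= clen:
                end = min(start + bin_len - 1, clen)
                bins.append(GenomicBin(chrom, start, end))
                start = end + 1
        return cls(bins=bins, contig_lengths=dict(lengths), bin_len=bin_len)

    def n_bins(self, chrom: str) -> int:
        return -(-self.contig_lengths[chrom] // self.bin_len)  # ceil division

    @property
    def contigs(self) -> list[str]:
        return list(self.contig_lengths)

    def contig_slice(self, chrom: str) -> slice:
        """Global column slice of one contig's bins."""
        offset = 0
        for name in self.contig_lengths:
            n = self.n_bins(name)
            if name == chrom:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(chrom)

    @property
    def labels(self) -> list[str]:
        return [f"{b.chrom}:{b.start}-{b.end}" for b in self.bins]

    def __len__(self) -> int:
        return len(self.bins)


def make_bins(genome, bin_len: int) -> BinSet:
    """Tile a genome (or a {contig: length} mapping) into bins."""
    lengths = genome if isinstance(genome, dict) else genome.lengths
    return BinSet.from_lengths(lengths, bin_len)


@dataclass
class SegmentSet:
    """Per-contig segment boundaries over a BinSet.

    ``boundaries[chrom]`` holds the sorted local bin indices at which a new
    segment starts (``seg_no - 1`` interior boundaries per contig).  The
    genomic breakpoint coordinate is the inclusive end of the last bin of
    the upstream segment — a multiple of ``bin_len`` for interior
    boundaries.
    """

    binset: BinSet
    boundaries: dict[str, tuple[int, ...]]

    def segments(self) -> list[tuple[str, int, int]]:
        """(chrom, first_local_bin, last_local_bin), genome order."""
        out = []
        for chrom in self.binset.contigs:
            nb = self.binset.n_bins(chrom)
            edges = [0, *self.boundaries[chrom], nb]
            for lo, hi in zip(edges[:-1], edges[1:]):
                out.append((chrom, lo, hi - 1))
        return out

    def breakpoints(self) -> list[tuple[str, int]]:
        """(chrom, genomic coordinate) of every interior boundary."""
        out = []
        for chrom in self.binset.contigs:
            sl = self.binset.contig_slice(chrom)
            contig_bins = self.binset.bins[sl]
            for b in self.boundaries[chrom]:
                out.append((chrom, contig_bins[b - 1].end))
        return out

    @property
    def n_segments(self) -> int:
        return sum(len(b) + 1 for b in self.boundaries.values())


def draw_segments(bins: BinSet, seg_no: int, rng: np.random.Generator) -> SegmentSet:
    """Draw ``seg_no - 1`` interior boundaries per contig, uniform w/o replacement."""
    boundaries = {}
    for chrom in bins.contigs:
        nb = bins.n_bins(chrom)
        if seg_no > nb:
            raise ValueError(
                f"seg_no={seg_no} exceeds {nb} bins on contig {chrom!r}"
            )
        if seg_no == 1:
            boundaries[chrom] = ()
        else:
            picks = rng.choice(np.arange(1, nb), size=seg_no - 1, replace=False)
            boundaries[chrom] = tuple(sorted(int(p) for p in picks))
    return SegmentSet(binset=bins, boundaries=boundaries)


def assign_clusters(
    cell_no: int,
    cluster_no: int,
    normal_frac: float,
    rng: np.random.Generator,
) -> list[str]:
    """Per-cell labels: ``normal`` or ``clone1..cloneK``.

    The first ``round(normal_frac * cell_no)`` cells are normal (stable
    labelling); each clone receives at least one tumor cell, the remainder
    are assigned i.i.d. uniformly.  ``cluster_no = 0`` makes every cell
    normal regardless of ``normal_frac``.
    """
    if cluster_no == 0:
        return ["normal"] * cell_no
    n_norm = round_half_away(normal_frac * cell_no)
    n_tumor = cell_no - n_norm
    if n_tumor < cluster_no:
        raise ValueError(
            f"infeasible clusters: {n_tumor} tumor cells < {cluster_no} clones"
        )
    clones = [f"clone{i + 1}" for i in range(cluster_no)]
    tumor_labels = clones + [
        clones[int(i)] for i in rng.integers(0, cluster_no, size=n_tumor - cluster_no)
    ]
    perm = rng.permutation(n_tumor)
    tumor_labels = [tumor_labels[int(i)] for i in perm]
    return ["normal"] * n_norm + tumor_labels


def draw_clone_profiles(
    segments: SegmentSet,
    cluster_no: int,
    max_cn: int,
    p_neutral: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One per-segment copy-number vector per clone.

    Each segment is neutral (CN=2) with probability ``p_neutral``, otherwise
    uniform over {0,1} U {3..max_cn}.  All-neutral and duplicate profiles
    are redrawn (bounded retries).
    """
    n_seg = segments.n_segments
    aberrant = np.array([0, 1] + list(range(3, max_cn + 1)))
    profiles: dict[str, np.ndarray] = {}
    seen: set[tuple[int, ...]] = set()
    for k in range(cluster_no):
        for attempt in range(1000):
            neutral = rng.random(n_seg) < p_neutral
            cn = rng.choice(aberrant, size=n_seg)
            cn[neutral] = 2
            if (cn == 2).all():
                continue
            key = tuple(int(v) for v in cn)
            if key in seen:
                continue
            seen.add(key)
            profiles[f"clone{k + 1}"] = cn.astype(np.int64)
            break
        else:
            raise RuntimeError(
                f"could not draw {cluster_no} distinct clone profiles "
                f"(seg_no may be too small for the CN alphabet)"
            )
    return profiles


@dataclass
class CNVMatrix:
    """Cells x bins integer copy numbers, clean and (optionally) noisy."""

    clean: np.ndarray
    cell_ids: list[str]
    bin_labels: list[str]
    noisy: np.ndarray | None = None


def build_matrix(
    assignment: list[str],
    clone_profiles: dict[str, np.ndarray],
    segments: SegmentSet,
    bins: BinSet,
) -> CNVMatrix:
    """Expand clone per-segment profiles to the per-bin clean matrix."""
    n_cells = len(assignment)
    per_bin: dict[str, np.ndarray] = {}
    seg_list = segments.segments()
    for clone, prof in clone_profiles.items():
        if len(prof) != len(seg_list):
            raise ValueError("clone profile length mismatches segment count")
        row = np.empty(len(bins), dtype=np.int64)
        for cn, (chrom, lo, hi) in zip(prof, seg_list):
            sl = bins.contig_slice(chrom)
            row[sl.start + lo : sl.start + hi + 1] = cn
        per_bin[clone] = row
    per_bin["normal"] = np.full(len(bins), 2, dtype=np.int64)
    clean = np.stack([per_bin[label] for label in assignment])
    return CNVMatrix(
        clean=clean,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
        bin_labels=bins.labels,
    )


def inject_noise(
    matrix: CNVMatrix,
    noise_rate: float,
    max_cn: int,
    rng: np.random.Generator,
) -> CNVMatrix:
    """Fill the noisy matrix: each entry moves +/-1 with probability noise_rate.

    A step that would leave [0, max_cn] flips direction instead, so a
    perturbed entry always differs from the clean one.  The clean matrix is
    untouched.
    """
    clean = matrix.clean
    mask = rng.random(clean.shape) < noise_rate
    step = np.where(rng.random(clean.shape) < 0.5, -1, 1)
    noisy = clean.copy()
    moved = clean + step
    moved = np.where(moved < 0, clean + 1, moved)
    moved = np.where(moved > max_cn, clean - 1, moved)
    noisy[mask] = moved[mask]
    matrix.noisy = noisy
    return matrix


def write_cnv_outputs(
    matrix: CNVMatrix,
    assignment: list[str],
    segments: SegmentSet,
    bins: BinSet,
    out_dir,
) -> dict[str, Path]:
    """Write matrices (CSV), clusters (CSV), breakpoints (TSV), segments (BED).

    Variant tables are 1-based inclusive; the BED file alone is 0-based
    half-open.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def write_matrix(arr, name):
        df = pd.DataFrame(arr, index=matrix.cell_ids, columns=matrix.bin_labels)
        path = out_dir / name
        df.to_csv(path, index_label="cell_id", lineterminator="\n")
        paths[name] = path

    write_matrix(matrix.clean, "cnv_matrix_clean.csv")
    if matrix.noisy is not None:
        write_matrix(matrix.noisy, "cnv_matrix_noisy.csv")

    path = out_dir / "clusters.csv"
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("cell_id,label\n")
        for cid, label in zip(matrix.cell_ids, assignment):
            fh.write(f"{cid},{label}\n")
    paths["clusters.csv"] = path

    path = out_dir / "breakpoints.tsv"
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in segments.breakpoints():
            fh.write(f"{chrom}\t{pos}\n")
    paths["breakpoints.tsv"] = path

    path = out_dir / "segments.bed"
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        seg_counter: dict[str, int] = {}
        for chrom, lo, hi in segments.segments():
            seg_counter[chrom] = seg_counter.get(chrom, 0) + 1
            sl = bins.contig_slice(chrom)
            start0 = bins.bins[sl.start + lo].start - 1
            end_excl = bins.bins[sl.start + hi].end
            fh.write(f"{chrom}\t{start0}\t{end_excl}\t{chrom}:seg{seg_counter[chrom]}\n")
    paths["segments.bed"] = path
    return paths
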