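"""FASTQ read simulation with depth proportional to copy number.

Per bin, the number of sequenced templates is Poisson with mean
``coverage * bin_width / bases_per_template * (cn / 2)`` — so a CN=2 bin is
covered at ``coverage``x and depth scales linearly with copy number, the
signal downstream CNV callers segment on.  Templates pick haplotype A or B
with probability 1/2, start uniformly within the haplotype-mapped bin
extent, and never straddle bin boundaries, which keeps per-bin counts
exactly Poisson and breakpoint depth steps sharp.  Substitution errors are
applied per base with probability ``error_rate``; qualities are a constant
Phred score.

Read names carry truth tags: ``cell|hap|contig|start|serial`` where
``start`` is the 1-based position of the read (or of the PE fragment) on
the named haplotype; paired-end mates additionally get ``/1``/``/2``
suffixes in the FASTQ.
"""

from __future__ import annotations

import gzip as gzip_mod
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cnv import BinSet
from .genome import HaplotypeGenome
from .params import SimulationParams

__all__ = ["ReadBatch", "expected_reads_per_bin", "simulate_cell_reads", "write_fastq"]

logger = logging.getLogger(__name__)

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_BASE_IDX = np.full(256, 4, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i
_IDX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadBatch:
    """Simulated reads of one cell; ``reads2`` is None for SE layouts."""

    cell_id: str
    layout: str
    names: list[str] = field(default_factory=list)
    reads1: list[str] = field(default_factory=list)
    reads2: list[str] | None = None
    quality: str = ""

    @property
    def n_templates(self) -> int:
        return len(self.reads1)


def expected_reads_per_bin(bin_width: int, cn: int, params: SimulationParams) -> float:
    """Poisson mean number of templates for one bin at copy number ``cn``."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    bases_per_template = params.read_len * (2 if params.layout == "PE" else 1)
    return params.coverage * bin_width / bases_per_template * (cn / 2.0)


def _apply_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator):
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    if not mask.any():
        return reads
    idx = _BASE_IDX[reads[mask]]
    shift = rng.integers(1, 4, size=idx.shape).astype(np.uint8)
    new = _IDX_BASE[(idx + shift) % 4]
    out = reads[mask]
    ok = idx < 4  # leave N bases untouched
    out[ok] = new[ok]
    reads[mask] = out
    return reads


def _rows_to_strings(arr: np.ndarray) -> list[str]:
    return [row.tobytes().decode("ascii") for row in arr]


def simulate_cell_reads(
    hap: HaplotypeGenome,
    cnv_row: np.ndarray,
    bins: BinSet,
    params: SimulationParams,
    rng: np.random.Generator,
) -> ReadBatch:
    """Generate one cell's reads from its haplotypes and CNV row.

    ``cnv_row`` holds the per-bin copy numbers (normally the noisy matrix
    row).  Bins whose haplotype-mapped extent is shorter than one template
    are skipped with a logged warning.  Deterministic per rng state.
    """
    if len(cnv_row) != len(bins):
        raise ValueError("cnv_row length mismatches the number of bins")
    pe = params.layout == "PE"
    read_len = params.read_len
    qual = chr(33 + params.base_quality) * read_len
    hap_bytes = {
        (h, name): np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for h, contigs in hap.haplotypes.items()
        for name, seq in contigs.items()
    }
    batch = ReadBatch(
        cell_id=hap.cell_id,
        layout=params.layout,
        reads2=[] if pe else None,
        quality=qual,
    )
    serial = 0
    for j, b in enumerate(bins.bins):
        cn = int(cnv_row[j])
        width = b.end - b.start + 1
        lam = expected_reads_per_bin(width, cn, params)
        if lam <= 0:
            continue
        n = int(rng.poisson(lam))
        hap_choice = rng.integers(0, 2, size=n)
        for h_idx, h_name in enumerate("AB"):
            count = int((hap_choice == h_idx).sum())
            if count == 0:
                continue
            cm = hap.coord_maps[(h_name, b.chrom)]
            extent = cm.map_range(b.start, b.end)
            min_template = 2 * read_len if pe else read_len
            if extent is None or extent[1] - extent[0] + 1 < min_template:
                logger.warning(
                    "cell %s bin %s:%d-%d hap %s: extent shorter than one "
                    "template; skipped",
                    hap.cell_id, b.chrom, b.start, b.end, h_name,
                )
                continue
            hs, he = extent
            ext_len = he - hs + 1
            seq_arr = hap_bytes[(h_name, b.chrom)]
            if pe:
                frags = np.rint(
                    rng.normal(params.insert_mean, params.insert_sd, size=count)
                ).astype(np.int64)
                frags = np.clip(frags, 2 * read_len, ext_len)
                starts = hs + np.floor(
                    rng.random(count) * (ext_len - frags + 1)
                ).astype(np.int64)
                r1 = seq_arr[(starts - 1)[:, None] + np.arange(read_len)]
                ends0 = starts + frags - read_len - 1
                r2 = seq_arr[ends0[:, None] + np.arange(read_len)]
                r2 = _COMP[r2][:, ::-1]
                r1 = _apply_errors(r1.copy(), params.error_rate, rng)
                r2 = _apply_errors(r2.copy(), params.error_rate, rng)
                batch.reads1.extend(_rows_to_strings(r1))
                batch.reads2.extend(_rows_to_strings(r2))
            else:
                starts = rng.integers(hs, he - read_len + 2, size=count)
                r1 = seq_arr[(starts - 1)[:, None] + np.arange(read_len)]
                r1 = _apply_errors(r1.copy(), params.error_rate, rng)
                batch.reads1.extend(_rows_to_strings(r1))
            for s in starts:
                batch.names.append(
                    f"{hap.cell_id}|{h_name}|{b.chrom}|{int(s)}|{serial}"
                )
                serial += 1
    return batch


def write_fastq(batch: ReadBatch, out_dir, gzip: bool = False) -> list[Path]:
    """Write the batch as Phred+33 FASTQ (SE: one file; PE: _1/_2 pair)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip else ".fastq"

    def opener(path):
        if gzip:
            return gzip_mod.open(path, "wt", encoding="ascii", newline="\n")
        return open(path, "w", encoding="ascii", newline="\n")

    paths = []
    if batch.layout == "PE":
        for mate, reads in ((1, batch.reads1), (2, batch.reads2)):
            path = out_dir / f"{batch.cell_id}_{mate}{ext}"
            with opener(path) as fh:
                for name, seq in zip(batch.names, reads):
                    fh.write(f"@{name}/{mate}\n{seq}\n+\n{batch.quality}\n")
            paths.append(path)
    else:
        path = out_dir / f"{batch.cell_id}{ext}"
        with opener(path) as fh:
            for name, seq in zip(batch.names, batch.reads1):
                fh.write(f"@{name}\n{seq}\n+\n{batch.quality}\n")
        paths.append(path)
    return paths
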