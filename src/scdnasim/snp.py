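"""Per-cell SNP profiles with a batch-shared core.

Each cell carries ``snp_no`` sites drawn from the SNP database.  A fraction
``shared_snp_frac`` (default 80%) of the sites form a core set common to
every cell in the batch — sampled once, genotypes drawn once, so shared
sites look identical across cells.  The remaining private sites are drawn
without replacement from the leftover pool and are disjoint across cells,
making the shared fraction exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from ._rng import child_rng
from .params import SimulationParams, round_half_away
from .refio import SNPDatabase

__all__ = ["SNPRecord", "CellSNPProfile", "SNPBatch", "simulate_snp_profiles",
           "write_snp_profiles"]

_HEADER = "cell_id\tchrom\tpos\trsid\tref\talt\tgenotype\n"


class SNPRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    rsid: str
    ref: str
    alt: str
    genotype: str  # "HET" or "HOM"


@dataclass
class CellSNPProfile:
    cell_id: str
    records: list[SNPRecord]


@dataclass
class SNPBatch:
    """All cell profiles plus the batch-shared core record set."""

    profiles: list[CellSNPProfile]
    shared: list[SNPRecord]


def _sort_key(db: SNPDatabase):
    order = {name: i for i, name in enumerate(db.chrom_order)}
    return lambda r: (order.get(r.chrom, len(order)), r.pos)


def simulate_snp_profiles(params: SimulationParams, db: SNPDatabase) -> SNPBatch:
    """Draw per-cell SNP profiles from the database.

    The shared core has exactly ``round(shared_snp_frac * snp_no)`` records;
    private records are pairwise disjoint across cells.  Genotypes are HET
    with probability ``het_rate`` (shared genotypes drawn once for the whole
    batch).  Deterministic per seed; adding cells never changes the draws of
    existing cells.
    """
    n_shared = round_half_away(params.shared_snp_frac * params.snp_no)
    n_priv = params.snp_no - n_shared
    need = n_shared + params.cell_no * n_priv
    if len(db) < need:
        raise ValueError(
            f"SNP database too small: need {need} records "
            f"({n_shared} shared + {params.cell_no} x {n_priv} private), "
            f"have {len(db)}"
        )
    rng = child_rng(params.seed, "snp/batch")
    perm = rng.permutation(len(db))
    shared_gt = ["HET" if u < params.het_rate else "HOM"
                 for u in rng.random(n_shared)]

    rows = list(db.df.itertuples(index=False))

    def make_record(row, gt) -> SNPRecord:
        return SNPRecord(row.chrom, int(row.pos), row.rsid, row.ref, row.alt, gt)

    shared = [make_record(rows[int(i)], gt)
              for i, gt in zip(perm[:n_shared], shared_gt)]
    key = _sort_key(db)
    shared_sorted = sorted(shared, key=key)

    profiles = []
    for c in range(params.cell_no):
        cell_rng = child_rng(params.seed, "snp", c)
        idx = perm[n_shared + c * n_priv : n_shared + (c + 1) * n_priv]
        gts = ["HET" if u < params.het_rate else "HOM"
               for u in cell_rng.random(n_priv)]
        private = [make_record(rows[int(i)], gt) for i, gt in zip(idx, gts)]
        records = sorted(shared + private, key=key)
        profiles.append(CellSNPProfile(cell_id=f"cell{c}", records=records))
    return SNPBatch(profiles=profiles, shared=shared_sorted)


def write_snp_profiles(batch: SNPBatch, out_dir) -> list[Path]:
    """Write one TSV per cell plus the batch-level shared-record TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for prof in batch.profiles:
        path = out_dir / f"{prof.cell_id}.snp.tsv"
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(_HEADER)
            for r in prof.records:
                fh.write(f"{prof.cell_id}\t{r.chrom}\t{r.pos}\t{r.rsid}\t"
                         f"{r.ref}\t{r.alt}\t{r.genotype}\n")
        paths.append(path)
    shared_path = out_dir / "shared.snp.tsv"
    with open(shared_path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(_HEADER)
        for r in batch.shared:
            fh.write(f"shared\t{r.chrom}\t{r.pos}\t{r.rsid}\t"
                     f"{r.ref}\t{r.alt}\t{r.genotype}\n")
    paths.append(shared_path)
    return paths
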