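"""Reference genome and SNP-database IO, plus synthetic fixture generators.

FASTA reading goes through Biopython; writing is a plain wrapped writer so
round trips are byte-exact.  The SNP database is a 5-column TSV dialect
(chrom, pos, rsid, ref, alt; 1-based positions; ``#`` header lines skipped)
for which a synthetic generator is bundled, so the full pipeline runs with
no external downloads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "SNPDatabase",
    "FastaError",
    "SNPTableError",
    "read_fasta",
    "write_fasta",
    "generate_synthetic_reference",
    "generate_synthetic_dbsnp",
    "parse_dbsnp_table",
    "write_dbsnp_table",
]

_VALID = set("ACGTN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FastaError(ValueError):
    pass


class SNPTableError(ValueError):
    pass


@dataclass
class ReferenceGenome:
    """An ordered set of named contigs over the alphabet {A,C,G,T,N}."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not name:
                raise FastaError("empty contig name")
            if not seq:
                raise FastaError(f"contig {name!r} has an empty sequence")
            bad = re.search(r"[^ACGTN]", seq)
            if bad:
                raise FastaError(
                    f"contig {name!r}: invalid character {bad.group()!r} "
                    f"at position {bad.start() + 1}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)


def read_fasta(path) -> ReferenceGenome:
    """Read a (possibly multi-contig, wrapped) FASTA into a ReferenceGenome.

    Headers are truncated at the first whitespace; sequence is uppercased.
    Rejects empty files, duplicate contig names and non-{A,C,G,T,N} bases.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in contigs:
            raise FastaError(f"duplicate contig name {name!r}")
        contigs[name] = str(rec.seq).upper()
    if not contigs:
        raise FastaError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path, line_width: int = 60) -> Path:
    """Write the genome as wrapped FASTA; inverse of :func:`read_fasta`."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if not genome.contigs:
        raise FastaError("refusing to write an empty genome")
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width])
                fh.write("\n")
    return path


def generate_synthetic_reference(
    n_contigs: int = 1,
    contig_len: int = 2_000_000,
    gc: float = 0.5,
    seed: int = 0,
) -> ReferenceGenome:
    """Generate an i.i.d. random reference with the given GC content.

    Bases are drawn with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2; no N bases.
    Contigs are named ``sim1``, ``sim2``, ...  Deterministic per seed.
    """
    if contig_len < 1:
        raise ValueError("contig_len must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    contigs = {}
    for i in range(n_contigs):
        arr = rng.choice(_BASES, size=contig_len, p=probs)
        contigs[f"sim{i + 1}"] = arr.tobytes().decode("ascii")
    return ReferenceGenome(contigs)


@dataclass
class SNPDatabase:
    """Known polymorphic sites: (chrom, pos, rsid, ref, alt), pos 1-based.

    Backed by a DataFrame sorted by (chrom-in-genome-order, pos); ref != alt
    and both are single bases in {A,C,G,T}.
    """

    df: pd.DataFrame

    COLUMNS = ("chrom", "pos", "rsid", "ref", "alt")

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @property
    def chrom_order(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


def _nonn_positions(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    """0-based indices of non-N bases per contig."""
    out = {}
    for name, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out[name] = np.nonzero(arr != ord("N"))[0]
    return out


def generate_synthetic_dbsnp(
    genome: ReferenceGenome, n_records: int, seed: int = 0
) -> SNPDatabase:
    """Sample ``n_records`` distinct SNP sites uniformly over non-N positions.

    ref is the reference base at the site; alt is uniform over the other
    three bases; rsids ``rsS000001``... are assigned after sorting by
    (chrom, pos).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    valid = _nonn_positions(genome)
    names = list(valid)
    counts = np.array([len(valid[n]) for n in names])
    total = int(counts.sum())
    if n_records > total:
        raise ValueError(
            f"n_records={n_records} exceeds {total} non-N reference positions"
        )
    flat = rng.choice(total, size=n_records, replace=False)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    rows = []
    for ci, name in enumerate(names):
        local = flat[(flat >= offsets[ci]) & (flat < offsets[ci + 1])] - offsets[ci]
        pos0 = np.sort(valid[name][local])
        seq = genome.contigs[name]
        for p0 in pos0:
            rows.append((name, int(p0) + 1, seq[p0]))
    refs = np.frombuffer("".join(r[2] for r in rows).encode("ascii"), dtype=np.uint8)
    ref_idx = np.searchsorted(_BASES, refs)
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(rows))) % 4
    alts = _BASES[alt_idx].tobytes().decode("ascii")
    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "rsid": [f"rsS{i + 1:06d}" for i in range(len(rows))],
            "ref": [r[2] for r in rows],
            "alt": list(alts),
        }
    )
    return SNPDatabase(df)


def write_dbsnp_table(db: SNPDatabase, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("#chrom\tpos\trsid\tref\talt\n")
        for row in db.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}\n")
    return path


def parse_dbsnp_table(path, genome: ReferenceGenome | None = None) -> SNPDatabase:
    """Parse the 5-column SNP TSV dialect; validate against ``genome`` if given.

    Malformed lines (wrong column count, non-integer position, multi-base
    or invalid alleles, ref == alt, duplicate sites) raise
    :class:`SNPTableError` with the line number.  When a genome is attached,
    records whose position exceeds the contig or whose ref base mismatches
    the reference are dropped; the count of dropped records is reported via
    the returned database's ``n_rejected`` attribute and a warning.
    """
    import warnings

    rows = []
    seen: set[tuple[str, int]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise SNPTableError(
                    f"line {lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            chrom, pos_s, rsid, ref, alt = parts
            try:
                pos = int(pos_s)
            except ValueError:
                raise SNPTableError(f"line {lineno}: non-integer position {pos_s!r}")
            if pos < 1:
                raise SNPTableError(f"line {lineno}: position must be >= 1")
            for allele, label in ((ref, "ref"), (alt, "alt")):
                if len(allele) != 1 or allele not in "ACGT":
                    raise SNPTableError(
                        f"line {lineno}: {label} allele {allele!r} must be a "
                        "single base in ACGT"
                    )
            if ref == alt:
                raise SNPTableError(f"line {lineno}: ref equals alt ({ref})")
            if (chrom, pos) in seen:
                raise SNPTableError(f"line {lineno}: duplicate site {chrom}:{pos}")
            seen.add((chrom, pos))
            rows.append((chrom, pos, rsid, ref, alt))
    n_rejected = 0
    if genome is not None:
        kept = []
        for row in rows:
            chrom, pos = row[0], row[1]
            seq = genome.contigs.get(chrom)
            if seq is None or pos > len(seq) or seq[pos - 1] != row[3]:
                n_rejected += 1
            else:
                kept.append(row)
        if n_rejected:
            warnings.warn(
                f"{n_rejected} SNP record(s) rejected: position out of range "
                "or ref base mismatching the reference",
                stacklevel=2,
            )
        rows = kept
    df = pd.DataFrame(rows, columns=list(SNPDatabase.COLUMNS))
    order = (
        {name: i for i, name in enumerate(genome.contigs)}
        if genome is not None
        else {name: i for i, name in enumerate(sorted(set(df["chrom"])))}
    )
    if len(df):
        df = (
            df.assign(_c=df["chrom"].map(order))
            .sort_values(["_c", "pos"])
            .drop(columns="_c")
            .reset_index(drop=True)
        )
    db = SNPDatabase(df)
    db.n_rejected = n_rejected
    return db
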