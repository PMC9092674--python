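"""The single parameter object that drives every simulator.

All four simulators (SNP, SNV, indel, CNV) and the read sampler consume one
immutable :class:`SimulationParams`.  Parameters can come from keyword
arguments, a flat ``KEY: value`` config file (a YAML-compatible subset), or
CLI flags; in all cases the object is checked by :func:`validate_params`
before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import yaml

__all__ = [
    "SimulationParams",
    "ParameterError",
    "ConfigError",
    "validate_params",
    "load_params",
    "round_half_away",
    "n_normal_cells",
]


class ParameterError(ValueError):
    """An invalid parameter value; ``field`` names the offending parameter."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ConfigError(ValueError):
    """A config file that cannot be parsed or contains unknown keys."""


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), for non-negative ``x``."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationParams:
    """Configuration for a simulated single-cell DNA-seq batch.

    Attributes
    ----------
    ref_path, snp_db_path, out_dir
        Input reference FASTA, optional SNP-database TSV, output directory.
    cell_no
        Number of cells per batch.
    snp_no, snv_no, indel_no
        Variants per cell for the three point-variant simulators.
    shared_snp_frac
        Fraction of each cell's SNPs drawn from a batch-shared core set
        (default 0.80, i.e. 80% of SNP sites are common to every cell).
    het_rate
        Probability that a variant is heterozygous (on one haplotype only).
    cluster_no, seg_no, normal_frac, p_neutral, noise_rate, bin_len, max_cn
        CNV model: number of tumor subclones, CNV segments per chromosome,
        fraction of normal (all-diploid) cells, per-segment probability of a
        neutral (CN=2) state in a clone profile, fraction of matrix entries
        perturbed by noise, bin width in bp, and copy-number ceiling.
    coverage
        Haploid-normalised mean depth: a CN=2 region is sequenced at
        ``coverage``x.
    read_len, layout, insert_mean, insert_sd
        Read geometry; ``layout`` is ``"SE"`` or ``"PE"``; the insert model
        applies to PE fragments only.
    error_rate, base_quality
        Per-base substitution error probability and the constant Phred score
        written to FASTQ quality strings.
    seed
        Global random seed; every stream derives from it.
    """

    ref_path: str | None = None
    snp_db_path: str | None = None
    out_dir: str = "scdnasim_out"
    cell_no: int = 10
    snp_no: int = 1000
    snv_no: int = 100
    indel_no: int = 100
    shared_snp_frac: float = 0.80
    het_rate: float = 0.5
    cluster_no: int = 2
    seg_no: int = 5
    normal_frac: float = 0.2
    p_neutral: float = 0.5
    noise_rate: float = 0.1
    bin_len: int = 500_000
    max_cn: int = 8
    coverage: float = 1.0
    read_len: int = 100
    layout: str = "SE"
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    base_quality: int = 30
    seed: int = 0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_INT_FIELDS = {
    "cell_no", "snp_no", "snv_no", "indel_no", "cluster_no", "seg_no",
    "bin_len", "max_cn", "read_len", "base_quality", "seed",
}
_FRAC_FIELDS = (
    "shared_snp_frac", "het_rate", "normal_frac", "noise_rate", "error_rate",
)


def n_normal_cells(p: SimulationParams) -> int:
    """Number of normal cells: round(normal_frac * cell_no), half away from 0."""
    return round_half_away(p.normal_frac * p.cell_no)


def validate_params(p: SimulationParams) -> SimulationParams:
    """Check every invariant; return ``p`` unchanged if all hold.

    Raises :class:`ParameterError` naming the first violated field.
    Idempotent and side-effect free.
    """
    for name in _INT_FIELDS:
        v = getattr(p, name)
        if isinstance(v, bool) or not isinstance(v, int):
            raise ParameterError(name, f"must be an integer, got {v!r}")
    for name in _FRAC_FIELDS:
        v = getattr(p, name)
        if not 0.0 <= float(v) <= 1.0:
            raise ParameterError(name, f"must lie in [0, 1], got {v}")
    if not 0.0 <= float(p.p_neutral) < 1.0:
        raise ParameterError("p_neutral", f"must lie in [0, 1), got {p.p_neutral}")
    if p.cell_no < 1:
        raise ParameterError("cell_no", "must be >= 1")
    for name in ("snp_no", "snv_no", "indel_no", "cluster_no", "seed"):
        if getattr(p, name) < 0:
            raise ParameterError(name, "must be >= 0")
    if p.seg_no < 1:
        raise ParameterError("seg_no", "must be >= 1")
    if p.read_len < 1:
        raise ParameterError("read_len", "must be >= 1")
    if p.bin_len < p.read_len:
        raise ParameterError("bin_len", f"must be >= read_len ({p.read_len})")
    if p.max_cn < 3:
        raise ParameterError("max_cn", "must be >= 3 (at least one gain state)")
    if not p.coverage > 0:
        raise ParameterError("coverage", "must be > 0")
    if p.layout not in ("SE", "PE"):
        raise ParameterError("layout", f"must be 'SE' or 'PE', got {p.layout!r}")
    if not p.insert_mean > 0:
        raise ParameterError("insert_mean", "must be > 0")
    if not p.insert_sd > 0:
        raise ParameterError("insert_sd", "must be > 0")
    if p.base_quality < 0 or p.base_quality > 93:
        raise ParameterError("base_quality", "must lie in [0, 93] (Phred+33)")
    if p.cluster_no > 0:
        if n_normal_cells(p) + p.cluster_no > p.cell_no:
            raise ParameterError(
                "cluster_no",
                f"infeasible clusters: {p.cell_no - n_normal_cells(p)} tumor "
                f"cells cannot host {p.cluster_no} non-empty clusters",
            )
    return p


def load_params(
    path: str, defaults: dict | None = None, **overrides
) -> SimulationParams:
    """Load a flat KEY: value config file; missing keys take defaults.

    ``defaults`` sit below the file (mode-specific baseline values);
    ``overrides`` (e.g. CLI flags) win over file values.  Unknown keys are
    rejected; the result always passes :func:`validate_params`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse config file{line}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must be a flat KEY: value mapping")
    known = {f.name for f in fields(SimulationParams)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    data = {**(defaults or {}), **data,
            **{k: v for k, v in overrides.items() if v is not None}}
    for key, value in data.items():
        if isinstance(value, (list, dict)):
            raise ConfigError(f"config key {key!r} must be a scalar")
    p = replace(SimulationParams(), **data)
    if p.layout is not None:
        p = replace(p, layout=str(p.layout).upper())
    return validate_params(p)
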