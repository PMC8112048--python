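"""Peptide-to-protein quantification for label-free proteomics.

The processing order is fixed and tracked by a scale tag on the study
object::

    rollup -> validity_filter -> normalize_length_run
           -> normalize_across_samples -> impute_lod

Peptide intensities are summed to proteins per sample; a protein's cell
is valid only with at least ``min_peptides`` distinct peptides and
``min_psms`` peptide-spectrum matches in that sample, and only when the
protein is valid in at least ``min_replicates`` replicates of its
(strain, timepoint) group.  Surviving intensities are divided by protein
length, each MS run is rescaled to a common total, values are log2
transformed and quantile normalized across samples, and remaining
missing values (assumed left-censored at the detection limit) are
imputed from a down-shifted, narrowed per-sample Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "QuantConfig",
    "AbundanceStudy",
    "validate_peptide_table",
    "rollup",
    "validity_filter",
    "normalize_length_run",
    "normalize_across_samples",
    "impute_lod",
    "quantify",
]

SCALES = ["raw", "normalized", "log2", "imputed"]

PEPTIDE_COLUMNS = ["peptide", "protein", "sample", "intensity", "psm_count"]


@dataclass
class QuantConfig:
    min_peptides: int = 2
    min_psms: int = 2
    min_replicates: int = 2
    replicates_per_group: int = 4
    lod_shift_sd: float = 1.8
    lod_width_sd: float = 0.3
    cross_sample_method: str = "quantile"  # or "median-center"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_peptides", "min_psms", "min_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lod_width_sd <= 0:
            raise ValueError("lod_width_sd must be positive")
        if self.cross_sample_method not in ("quantile", "median-center"):
            raise ValueError("cross_sample_method must be 'quantile' or 'median-center'")


@dataclass
class AbundanceStudy:
    """Protein-by-sample abundance matrix with metadata.

    ``matrix`` is a DataFrame indexed by protein id with one column per
    sample id (NaN = missing).  ``samples`` carries strain / timepoint /
    replicate / phase per sample; ``proteins`` carries length_aa, is_puf
    and annotation per protein.  ``imputed_mask`` records which cells
    were filled by LOD imputation (all-False before that stage).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame
    scale: str = "raw"
    imputed_mask: pd.DataFrame | None = None
    filter_report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns must match sample metadata index")
        missing = set(self.matrix.index) - set(self.proteins.index)
        if missing:
            raise ValueError(f"proteins without records: {sorted(missing)[:5]} ...")
        dup = self.samples.duplicated(subset=["strain", "timepoint", "replicate"])
        if dup.any():
            raise ValueError("duplicate (strain, timepoint, replicate) in samples")

    def _advance(self, new_scale: str, **kw) -> "AbundanceStudy":
        if SCALES.index(new_scale) <= SCALES.index(self.scale):
            raise ValueError(f"scale may only move forward, {self.scale} -> {new_scale}")
        return replace(self, scale=new_scale, **kw)

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Sample ids per (strain, timepoint)."""
        out: dict[tuple[str, str], list[str]] = {}
        for sid, row in self.samples.iterrows():
            out.setdefault((row["strain"], row["timepoint"]), []).append(sid)
        return out


def validate_peptide_table(peptides: pd.DataFrame) -> pd.DataFrame:
    """Check peptide-table schema and invariants; returns the typed table."""
    missing = set(PEPTIDE_COLUMNS) - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    df = peptides[PEPTIDE_COLUMNS].copy()
    if df.duplicated(subset=["peptide", "protein", "sample"]).any():
        raise ValueError("duplicate (peptide, protein, sample) rows")
    if (df["intensity"].dropna() < 0).any():
        raise ValueError("negative peptide intensity")
    psm = df["psm_count"]
    if not np.allclose(psm, np.round(psm)) or (psm < 0).any():
        raise ValueError("psm_count must be a non-negative integer")
    df["psm_count"] = psm.astype(int)
    if (df.loc[df["intensity"].isna(), "psm_count"] > 0).any():
        raise ValueError("missing intensity with psm_count > 0")
    return df


def rollup(peptides: pd.DataFrame, samples: pd.DataFrame,
           proteins: pd.DataFrame) -> tuple[AbundanceStudy, pd.DataFrame]:
    """Sum peptide intensities to proteins per sample.

    Returns the raw-scale study plus a per-(protein, sample) count table
    with columns ``n_peptides`` (distinct peptides with an observed
    intensity) and ``n_psms``.  A protein/sample cell is missing iff all
    of its peptides are missing there.
    """
    df = validate_peptide_table(peptides)
    unknown = set(df["protein"]) - set(proteins.index)
    if unknown:
        raise ValueError(f"peptides reference unknown proteins: {sorted(unknown)[:5]}")
    present = df.dropna(subset=["intensity"])
    grouped = present.groupby(["protein", "sample"], sort=False)
    sums = grouped["intensity"].sum()
    counts = grouped.agg(n_peptides=("peptide", "nunique"),
                         n_psms=("psm_count", "sum")).reset_index()
    matrix = sums.unstack("sample").reindex(
        index=proteins.index, columns=samples.index)
    study = AbundanceStudy(matrix=matrix, samples=samples, proteins=proteins,
                           scale="raw")
    return study, counts


def validity_filter(study: AbundanceStudy, counts: pd.DataFrame,
                    config: QuantConfig | None = None) -> AbundanceStudy:
    """Apply the per-sample evidence rule and the replicate rule.

    A cell survives only with ``>= min_peptides`` distinct peptides and
    ``>= min_psms`` PSMs in that sample; within each (strain, timepoint)
    group a protein must be valid in ``>= min_replicates`` replicates or
    the whole group is set missing.  Proteins left with no observed cell
    are dropped, with reasons collected in ``filter_report``.
    """
    config = config or QuantConfig()
    valid = counts[(counts["n_peptides"] >= config.min_peptides)
                   & (counts["n_psms"] >= config.min_psms)]
    mask = pd.DataFrame(False, index=study.matrix.index,
                        columns=study.matrix.columns)
    rows = mask.index.get_indexer(valid["protein"])
    cols = mask.columns.get_indexer(valid["sample"])
    keep = (rows >= 0) & (cols >= 0)
    mask.values[rows[keep], cols[keep]] = True

    for (strain, tp), sids in study.groups().items():
        n_expected = config.replicates_per_group
        if len(sids) < n_expected:
            import warnings
            warnings.warn(
                f"group ({strain}, {tp}) has {len(sids)} replicates, "
                f"expected {n_expected}; applying rule to the available count")
        ok = mask[sids].sum(axis=1) >= config.min_replicates
        mask.loc[~ok, sids] = False

    filtered = study.matrix.where(mask)
    observed = filtered.notna().any(axis=1)
    report = pd.DataFrame({
        "protein": filtered.index[~observed],
        "reason": "no group with sufficient peptide/PSM evidence",
    })
    return replace(study, matrix=filtered.loc[observed],
                   proteins=study.proteins.loc[observed[observed].index],
                   filter_report=report)


def normalize_length_run(study: AbundanceStudy) -> AbundanceStudy:
    """Divide by protein length, then rescale each run to a common total."""
    if study.scale != "raw":
        raise ValueError("length/run normalization expects a raw-scale study")
    lengths = study.proteins.loc[study.matrix.index, "length_aa"]
    if (lengths < 1).any():
        raise ValueError("protein lengths must be >= 1")
    per_length = study.matrix.div(lengths, axis=0)
    totals = per_length.sum(axis=0, skipna=True)
    empty = totals[per_length.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"sample(s) with no observed values: {list(empty.index)}")
    scaled = per_length.mul(totals.mean() / totals, axis=1)
    return study._advance("normalized", matrix=scaled)


def _quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize present values; missing cells stay missing.

    The reference quantile function is the average of the per-sample
    empirical quantile functions on mid-rank fractions; samples with
    equal numbers of present values therefore map exactly onto the
    rank-wise mean of their sorted values.
    """
    X = matrix.to_numpy(dtype=float)
    n_obs = (~np.isnan(X)).sum(axis=0)
    grid_n = int(n_obs.max())
    grid = (np.arange(grid_n) + 0.5) / grid_n
    curves = np.empty((X.shape[1], grid_n))
    for j in range(X.shape[1]):
        v = np.sort(X[~np.isnan(X[:, j]), j])
        frac = (np.arange(len(v)) + 0.5) / len(v)
        curves[j] = np.interp(grid, frac, v)
    reference = curves.mean(axis=0)
    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        obs = ~np.isnan(X[:, j])
        order = np.argsort(X[obs, j], kind="stable")
        frac = (np.arange(order.size) + 0.5) / order.size
        mapped = np.interp(frac, grid, reference)
        col = np.empty(order.size)
        col[order] = mapped
        out[obs, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_across_samples(study: AbundanceStudy,
                             config: QuantConfig | None = None) -> AbundanceStudy:
    """log2 transform, then equalize sample distributions.

    Default is quantile normalization of present values; the alternative
    ``median-center`` subtracts each sample's median log2 abundance.
    """
    config = config or QuantConfig()
    if study.scale != "normalized":
        raise ValueError("cross-sample normalization expects a length/run-normalized study")
    if (study.matrix <= 0).any().any():
        raise ValueError("non-positive intensities cannot be log2 transformed")
    logged = np.log2(study.matrix)
    if study.matrix.shape[1] == 1:
        out = logged
    elif config.cross_sample_method == "quantile":
        out = _quantile_normalize(logged)
    else:
        out = logged.sub(logged.median(axis=0), axis=1)
    return study._advance("log2", matrix=out)


def impute_lod(study: AbundanceStudy, config: QuantConfig | None = None) -> AbundanceStudy:
    """Fill missing cells with draws mimicking the detection limit.

    Each missing cell in sample ``s`` is drawn from
    ``Normal(mu_s - lod_shift_sd * sd_s, (lod_width_sd * sd_s)^2)`` where
    ``mu_s`` and ``sd_s`` are the sample's observed mean and SD.
    Observed cells are untouched and the imputed mask is recorded.
    """
    config = config or QuantConfig()
    if study.scale != "log2":
        raise ValueError("imputation expects a log2-normalized study")
    rng = np.random.default_rng(config.seed)
    X = study.matrix.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    for j, sid in enumerate(study.matrix.columns):
        obs = X[~mask[:, j], j]
        if mask[:, j].sum() == 0:
            continue
        if obs.size < 3:
            raise ValueError(f"sample {sid} has fewer than 3 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        loc = mu - config.lod_shift_sd * sd
        scale = config.lod_width_sd * sd
        X[mask[:, j], j] = rng.normal(loc, scale, size=int(mask[:, j].sum()))
    matrix = pd.DataFrame(X, index=study.matrix.index, columns=study.matrix.columns)
    mask_df = pd.DataFrame(mask, index=study.matrix.index,
                           columns=study.matrix.columns)
    return study._advance("imputed", matrix=matrix, imputed_mask=mask_df)


def quantify(peptides: pd.DataFrame, samples: pd.DataFrame, proteins: pd.DataFrame,
             config: QuantConfig | None = None) -> AbundanceStudy:
    """Run the full quantification chain in its fixed order."""
    config = config or QuantConfig()
    study, counts = rollup(peptides, samples, proteins)
    study = validity_filter(study, counts, config)
    study = normalize_length_run(study)
    study = normalize_across_samples(study, config)
    return impute_lod(study, config)
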