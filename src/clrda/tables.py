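"""Count-table and metadata handling: the shared tabular data model.

Two objects flow through every analysis: a :class:`CountTable` holding a
taxa-by-samples matrix of non-negative integer read counts (entry ``Y[i, s]``
for taxon *i* in sample *s*, with library size ``N_s`` the column sum), and a
:class:`SampleFrame` holding, for each sample, the covariate of interest
``u``, numeric adjustment covariates, and an optional subject label for
correlated designs.

Tables are read from delimited text (TSV/CSV).  Counts are canonicalized to
taxa-as-rows internally; both orientations are accepted on input.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input table violates the data model."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# CountTable


@dataclass
class CountTable:
    """Taxa-by-samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        Integer matrix with shape ``(len(taxon_ids), len(sample_ids))``.
    taxon_ids, sample_ids
        Unique row and column identifiers.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts contain non-numeric entries")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (arr < 0).any():
            i, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(np.mod(arr, 1) != 0):
            i, s = np.argwhere(np.mod(arr, 1) != 0)[0]
            raise ValidationError(
                f"non-integer count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = arr.astype(np.int64)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if arr.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"({len(self.taxon_ids)} taxa, {len(self.sample_ids)} samples)"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {name} IDs: {dup}")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total read count ``N_s`` (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def select(self, taxa=None, samples=None) -> "CountTable":
        """Subset by integer indices, preserving order."""
        ti = np.arange(self.m) if taxa is None else np.asarray(taxa)
        si = np.arange(self.n) if samples is None else np.asarray(samples)
        return CountTable(
            self.counts[np.ix_(ti, si)],
            [self.taxon_ids[i] for i in ti],
            [self.sample_ids[s] for s in si],
        )


def read_counts(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a delimited count matrix (header row, first-column IDs).

    ``orientation="samples_rows"`` accepts the transposed layout; the result
    is always taxa-as-rows.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # noqa: BLE001 - surface as validation failure
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    if orientation == "samples_rows":
        df = df.T
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric cell(s) in column {col!r}: rows {list(bad.index[:3])}"
            )
    return CountTable.from_dataframe(df)


def write_counts(ct: CountTable, path) -> None:
    ct.to_dataframe().to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# SampleFrame


@dataclass
class SampleFrame:
    """Per-sample covariates aligned to a :class:`CountTable`.

    ``u`` is the single covariate of interest (binary coded 0/1 or
    continuous).  ``covariates`` is an ``n x d`` numeric frame of adjustment
    covariates with categorical variables already expanded to indicator
    columns (reference level dropped).  ``subject`` optionally groups
    samples for random-intercept models.
    """

    sample_ids: list[str]
    u: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    subject: np.ndarray | None = None
    var_name: str = "u"

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in metadata")
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (len(self.sample_ids),):
            raise ValidationError("u must have one value per sample")
        if np.isnan(self.u).any():
            raise ValidationError(f"missing values in covariate {self.var_name!r}")
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=self.sample_ids)
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariates must have one row per sample")
        if self.covariates.isna().any().any():
            bad = list(self.covariates.columns[self.covariates.isna().any()])
            raise ValidationError(f"missing values in adjustment covariates {bad}")
        if self.subject is not None:
            self.subject = np.asarray([str(g) for g in self.subject])
            if self.subject.shape != (len(self.sample_ids),):
                raise ValidationError("subject must have one label per sample")
            if any(g in ("", "nan", "None") for g in self.subject):
                raise ValidationError("empty subject label")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def d(self) -> int:
        return self.covariates.shape[1]

    def reindex(self, ids: list[str]) -> "SampleFrame":
        """Restrict and reorder to ``ids`` (all must be present)."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return SampleFrame(
            list(ids),
            self.u[idx],
            self.covariates.iloc[idx],
            None if self.subject is None else self.subject[idx],
            self.var_name,
        )


def read_metadata(
    path,
    var: str,
    adjust: tuple[str, ...] = (),
    group: str | None = None,
    sample_ids: list[str] | None = None,
) -> SampleFrame:
    """Read sample metadata keyed by sample ID.

    ``var`` names the covariate of interest; ``adjust`` the adjustment
    columns (categoricals are expanded to indicators, reference level
    dropped); ``group`` an optional subject column for random effects.  When
    ``sample_ids`` is given (typically from the count table) the frame is
    restricted and ordered to the intersection.
    """
    md = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    md.index = md.index.astype(str)
    for col in (var, *adjust, *((group,) if group else ())):
        if col not in md.columns:
            raise ValidationError(f"column {col!r} not found in {path}")
    if sample_ids is not None:
        keep = [s for s in sample_ids if s in md.index]
        if not keep:
            raise ValidationError("no overlap between count-table and metadata samples")
        md = md.loc[keep]

    uc = md[var]
    if pd.api.types.is_numeric_dtype(uc):
        u = uc.to_numpy(dtype=float)
    else:
        levels = sorted(uc.dropna().astype(str).unique())
        if len(levels) != 2:
            raise ValidationError(
                f"non-numeric covariate {var!r} must have exactly 2 levels, got {levels}"
            )
        u = (uc.astype(str) == levels[1]).astype(float).to_numpy()
        warnings.warn(f"covariate {var!r} coded 0={levels[0]}, 1={levels[1]}")
        u[uc.isna().to_numpy()] = np.nan

    pieces = []
    for col in adjust:
        c = md[col]
        if pd.api.types.is_numeric_dtype(c):
            pieces.append(c.astype(float).to_frame())
        else:
            dummies = pd.get_dummies(c.astype(str), prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
    C = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=md.index)

    subject = None
    if group is not None:
        if md[group].isna().any():
            raise ValidationError(f"missing values in group column {group!r}")
        subject = md[group].astype(str).to_numpy()
        if len(np.unique(subject)) == len(md):
            warnings.warn(
                f"group column {group!r} has one subject per sample; "
                "random effects will be degenerate"
            )
    return SampleFrame(list(md.index), u, C, subject, var_name=var)


# ---------------------------------------------------------------------------
# Filtering and winsorization


@dataclass
class FilterReport:
    """Record of what :func:`filter_table` kept and dropped."""

    kept_samples: list[str]
    dropped_samples: list[str]
    kept_taxa: list[str]
    dropped_taxa: list[str]
    min_lib: int
    min_prev: float

    def to_dict(self) -> dict:
        return {
            "min_lib": self.min_lib,
            "min_prev": self.min_prev,
            "n_kept_samples": len(self.kept_samples),
            "n_dropped_samples": len(self.dropped_samples),
            "n_kept_taxa": len(self.kept_taxa),
            "n_dropped_taxa": len(self.dropped_taxa),
            "dropped_samples": self.dropped_samples,
            "dropped_taxa": self.dropped_taxa,
        }


def filter_table(
    ct: CountTable, min_lib: int = 1000, min_prev: float = 0.10
) -> tuple[CountTable, FilterReport]:
    """Drop samples with library size below ``min_lib``, then taxa present
    (nonzero) in fewer than ``min_prev`` of the remaining samples.

    Samples are filtered first so that prevalence refers to analyzable
    samples.
    """
    libs = ct.library_sizes
    keep_s = np.flatnonzero(libs >= min_lib)
    if keep_s.size == 0:
        raise ValidationError(f"all samples have library size < {min_lib}")
    sub = ct.counts[:, keep_s]
    prev = (sub > 0).mean(axis=1)
    keep_t = np.flatnonzero(prev >= min_prev)
    out = ct.select(keep_t, keep_s)
    report = FilterReport(
        kept_samples=out.sample_ids,
        dropped_samples=[ct.sample_ids[s] for s in np.setdiff1d(np.arange(ct.n), keep_s)],
        kept_taxa=out.taxon_ids,
        dropped_taxa=[ct.taxon_ids[i] for i in np.setdiff1d(np.arange(ct.m), keep_t)],
        min_lib=min_lib,
        min_prev=min_prev,
    )
    return out, report


def winsorize(ct: CountTable, q: float = 0.97) -> CountTable:
    """Cap extreme per-taxon relative abundances at their ``q``-quantile.

    For each taxon, proportions ``Y[i, s] / N_s`` above the empirical
    ``q``-quantile (linear-interpolation definition, :func:`numpy.quantile`
    default) are capped at that quantile and counts reconstructed as
    ``round(capped proportion * N_s)``.  Counts at or below the quantile are
    unchanged; ``q = 1`` is the identity.
    """
    if not 0 < q <= 1:
        raise ValueError(f"winsorization quantile must be in (0, 1], got {q}")
    if q == 1:
        return CountTable(ct.counts.copy(), list(ct.taxon_ids), list(ct.sample_ids))
    libs = ct.library_sizes.astype(float)
    safe = np.where(libs > 0, libs, 1.0)
    props = ct.counts / safe
    cutoff = np.quantile(props, q, axis=1, keepdims=True)
    capped = np.where(props > cutoff, cutoff, props)
    counts = np.where(props > cutoff, np.rint(capped * safe), ct.counts)
    return CountTable(counts.astype(np.int64), list(ct.taxon_ids), list(ct.sample_ids))
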