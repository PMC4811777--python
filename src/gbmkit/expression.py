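"""Expression-matrix preprocessing and fold-change "rescue" classification.

The stage mirrors a standard bead-array workflow: a variance-stabilizing
(generalized-log) transform of raw intensities, quantile normalization across
samples, averaging of technical duplicates (with a Pearson-correlation QC
check), per-condition mean log2 fold changes against a reference condition,
selection of deregulated genes at a fold threshold, and classification of
which deregulated genes are "rescued" (return into the fold band) in a second
comparison condition.

Containers are thin dataclasses around :class:`pandas.DataFrame` /
:class:`pandas.Series`; the two reusable transforms are sklearn-style
estimators (:class:`GlogTransformer`, :class:`QuantileNormalizer`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "FoldChangeProfile",
    "DeregulatedGeneSet",
    "GlogTransformer",
    "QuantileNormalizer",
    "vst_transform",
    "quantile_normalize",
    "collapse_duplicates",
    "fold_change_profile",
    "select_deregulated",
    "classify_rescue",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample. Raw-scale
        values must be strictly positive; no missing values are allowed.
    scale
        ``"raw"`` (positive intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.data.isna().any().any():
            gene, sample = _first_offender(self.data.isna())
            raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
        if self.scale == "raw" and (self.data.values <= 0).any():
            gene, sample = _first_offender(self.data <= 0)
            raise ValueError(
                f"non-positive raw intensity at gene {gene!r}, sample {sample!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return gene, sample


@dataclass
class SampleAnnotation:
    """Sample-level annotation: condition and technical-replicate grouping.

    ``frame`` needs columns ``sample_id``, ``condition`` and
    ``replicate_group``; ``reference`` names the reference condition
    (typically wild-type).
    """

    frame: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate_group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"annotation is missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in annotation")
        if self.reference not in set(self.frame["condition"]):
            raise ValueError(
                f"reference condition {self.reference!r} has no samples"
            )

    def require_samples(self, sample_ids) -> None:
        missing = set(sample_ids) - set(self.frame["sample_id"])
        if missing:
            raise ValueError(f"samples not annotated: {sorted(missing)[:5]}")

    def condition_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        return row["condition"].iloc[0]


@dataclass
class FoldChangeProfile:
    """Per-gene mean log2 fold change of ``condition`` versus ``reference``."""

    values: pd.Series
    condition: str
    reference: str

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate genes in fold-change profile")


@dataclass
class DeregulatedGeneSet:
    """Genes passing the fold threshold, with optional rescue flags.

    ``frame`` columns: ``gene``, ``direction`` (up/down), ``logfc_primary``
    and, once :func:`classify_rescue` has run, ``logfc_secondary`` and
    ``rescued``. ``summary`` carries up/down counts and rescue fractions.
    """

    frame: pd.DataFrame
    fold_threshold: float = 1.5
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# variance-stabilizing (generalized-log) transform
# ---------------------------------------------------------------------------


class GlogTransformer(TransformerMixin, BaseEstimator):
    """Generalized-log transform ``log2((x + sqrt(x^2 + c^2)) / 2)``.

    With ``c = 0`` this is a plain ``log2``; ``c > 0`` damps the variance of
    low-intensity values, the usual variance-stabilizing behaviour for array
    intensities. The transform is strictly increasing in ``x`` for any ``c``,
    so within-sample rankings are preserved.
    """

    def __init__(self, glog_c: float = 0.0):
        self.glog_c = glog_c

    def fit(self, X, y=None):
        if self.glog_c < 0:
            raise ValueError(f"glog_c must be >= 0, got {self.glog_c}")
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else None
        return self

    def transform(self, X):
        if self.glog_c < 0:
            raise ValueError(f"glog_c must be >= 0, got {self.glog_c}")
        values = np.asarray(X, dtype=float)
        out = np.log2((values + np.sqrt(values**2 + self.glog_c**2)) / 2.0)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def vst_transform(matrix: ExpressionMatrix, glog_c: float = 0.0) -> ExpressionMatrix:
    """Apply the generalized-log transform to a raw-scale matrix.

    Raises with the gene/sample coordinates of the first offending entry if
    any raw value is non-positive (that check already runs at construction,
    and is repeated here so a hand-built DataFrame cannot slip through).
    """
    if matrix.scale != "raw":
        raise ValueError("vst_transform expects a raw-scale matrix")
    if (matrix.data.values <= 0).any():
        gene, sample = _first_offender(matrix.data <= 0)
        raise ValueError(f"non-positive value at gene {gene!r}, sample {sample!r}")
    out = GlogTransformer(glog_c=glog_c).fit_transform(matrix.data)
    return ExpressionMatrix(out, scale="log2")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization across samples (columns).

    ``fit`` computes the reference distribution — the across-sample mean of
    the sorted value vectors; ``transform`` replaces each sample's values by
    the reference value of matching rank. Ties within a sample receive the
    mean of the reference values their ranks span (mid-rank rule), so the
    transform is well defined and idempotent.
    """

    def fit(self, X, y=None):
        values = self._as_array(X)
        if values.shape[1] < 2:
            raise ValueError("quantile normalization needs at least 2 samples")
        self.reference_ = np.sort(values, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        values = self._as_array(X)
        if values.shape[0] != self.reference_.shape[0]:
            raise ValueError(
                f"matrix has {values.shape[0]} genes but the reference "
                f"distribution was fitted on {self.reference_.shape[0]}"
            )
        out = np.empty_like(values, dtype=float)
        ref = self.reference_
        for j in range(values.shape[1]):
            col = values[:, j]
            order = np.argsort(col, kind="mergesort")
            mapped = np.empty_like(ref)
            mapped[order] = ref
            # mid-rank tie rule: equal input values share the mean of the
            # reference values their positions span
            out[:, j] = pd.Series(mapped).groupby(col, sort=False).transform("mean")
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    @staticmethod
    def _as_array(X) -> np.ndarray:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D genes x samples matrix")
        return values


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Jointly quantile-normalize a log2-scale matrix across its samples."""
    if matrix.scale != "log2":
        raise ValueError("quantile_normalize expects a log2-scale matrix")
    out = QuantileNormalizer().fit_transform(matrix.data)
    return ExpressionMatrix(out, scale="log2")


# ---------------------------------------------------------------------------
# technical duplicates
# ---------------------------------------------------------------------------


def collapse_duplicates(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    min_corr: float = 0.996,
    strict: bool = False,
) -> tuple[ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Average technical duplicates into one column per replicate group.

    Returns the collapsed matrix (columns named by replicate group, in first-
    appearance order), a collapsed annotation (one row per group), and a QC
    report with the Pearson correlation of every duplicate pair. Pairs below
    ``min_corr`` are flagged; by default that is a warning, with
    ``strict=True`` it is an error. A replicate group spanning two conditions
    is always an error.
    """
    annotation.require_samples(matrix.sample_ids)
    ann = annotation.frame.set_index("sample_id").loc[matrix.sample_ids]

    records = []
    collapsed_cols: dict[str, np.ndarray] = {}
    group_condition: dict[str, str] = {}
    for group, members in ann.groupby("replicate_group", sort=False):
        conditions = members["condition"].unique()
        if len(conditions) > 1:
            raise ValueError(
                f"replicate group {group!r} spans conditions {sorted(conditions)}"
            )
        group_condition[str(group)] = conditions[0]
        cols = matrix.data[members.index].to_numpy(dtype=float)
        collapsed_cols[str(group)] = cols.mean(axis=1)
        member_ids = list(members.index)
        for i in range(len(member_ids)):
            for k in range(i + 1, len(member_ids)):
                r = float(np.corrcoef(cols[:, i], cols[:, k])[0, 1])
                flagged = r < min_corr
                records.append(
                    {
                        "replicate_group": group,
                        "sample_a": member_ids[i],
                        "sample_b": member_ids[k],
                        "pearson_r": r,
                        "flagged": flagged,
                    }
                )
                if flagged:
                    msg = (
                        f"duplicate pair ({member_ids[i]}, {member_ids[k]}) has "
                        f"correlation {r:.4f} < {min_corr}"
                    )
                    if strict:
                        raise ValueError(msg)
                    warnings.warn(msg, stacklevel=2)

    collapsed = pd.DataFrame(collapsed_cols, index=matrix.gene_ids)
    report = pd.DataFrame(
        records,
        columns=["replicate_group", "sample_a", "sample_b", "pearson_r", "flagged"],
    )
    new_ann = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": list(collapsed.columns),
                "condition": [group_condition[g] for g in collapsed.columns],
                "replicate_group": list(collapsed.columns),
            }
        ),
        reference=annotation.reference,
    )
    return ExpressionMatrix(collapsed, scale=matrix.scale), new_ann, report


# ---------------------------------------------------------------------------
# fold changes, deregulation, rescue
# ---------------------------------------------------------------------------


def fold_change_profile(
    matrix: ExpressionMatrix, annotation: SampleAnnotation, condition: str
) -> FoldChangeProfile:
    """Mean log2 fold change of ``condition`` samples versus the reference."""
    if matrix.scale != "log2":
        raise ValueError("fold changes are computed on the log2 scale")
    if condition == annotation.reference:
        raise ValueError("condition must differ from the reference")
    ann = annotation.frame.set_index("sample_id")
    known = set(ann["condition"])
    if condition not in known:
        raise ValueError(f"unknown condition {condition!r}; known: {sorted(known)}")
    cond_ids = [s for s in matrix.sample_ids if ann.loc[s, "condition"] == condition]
    ref_ids = [
        s for s in matrix.sample_ids if ann.loc[s, "condition"] == annotation.reference
    ]
    if not cond_ids or not ref_ids:
        raise ValueError("both condition and reference groups must be non-empty")
    logfc = matrix.data[cond_ids].mean(axis=1) - matrix.data[ref_ids].mean(axis=1)
    return FoldChangeProfile(logfc, condition=condition, reference=annotation.reference)


def select_deregulated(
    profile: FoldChangeProfile, fold_threshold: float = 1.5
) -> DeregulatedGeneSet:
    """Select genes deregulated more than ``fold_threshold``-fold.

    A gene is included iff ``|logFC| > log2(fold_threshold)`` (strict — "more
    than 1.5-fold"); direction is the sign of the fold change. Gene order of
    the input profile is preserved.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    cut = np.log2(fold_threshold)
    mask = profile.values.abs() > cut
    selected = profile.values[mask]
    frame = pd.DataFrame(
        {
            "gene": selected.index,
            "direction": np.where(selected.values > 0, "up", "down"),
            "logfc_primary": selected.values,
        }
    ).reset_index(drop=True)
    summary = {
        "n_up": int((frame["direction"] == "up").sum()),
        "n_down": int((frame["direction"] == "down").sum()),
        "fold_threshold": fold_threshold,
        "condition": profile.condition,
        "reference": profile.reference,
    }
    return DeregulatedGeneSet(frame, fold_threshold=fold_threshold, summary=summary)


def classify_rescue(
    dereg: DeregulatedGeneSet,
    secondary_profile: FoldChangeProfile,
    fold_threshold: float = 1.5,
) -> DeregulatedGeneSet:
    """Flag deregulated genes whose secondary fold change is back in band.

    A gene is rescued iff ``|secondary logFC| <= log2(fold_threshold)``
    (non-strict: the complement of the strict deregulation region), i.e. the
    second comparison no longer shows the deregulation. The summary reports
    rescued/total per direction and the overall rescued fraction.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    missing = set(dereg.frame["gene"]) - set(secondary_profile.values.index)
    if missing:
        raise ValueError(
            f"deregulated genes missing from secondary profile: {sorted(missing)[:5]}"
        )
    cut = np.log2(fold_threshold)
    frame = dereg.frame.copy()
    frame["logfc_secondary"] = secondary_profile.values.loc[frame["gene"]].values
    frame["rescued"] = frame["logfc_secondary"].abs() <= cut

    summary = dict(dereg.summary)
    total = len(frame)
    for direction in ("up", "down"):
        sub = frame[frame["direction"] == direction]
        summary[f"rescued_{direction}"] = int(sub["rescued"].sum())
        summary[f"total_{direction}"] = int(len(sub))
    summary["rescued_total"] = int(frame["rescued"].sum())
    summary["rescued_fraction"] = (
        float(frame["rescued"].sum()) / total if total else float("nan")
    )
    summary["secondary_condition"] = secondary_profile.condition
    return DeregulatedGeneSet(frame, fold_threshold=dereg.fold_threshold, summary=summary)
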