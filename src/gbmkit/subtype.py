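"""Cross-species nearest-centroid GBM-subtype assignment with a simulation test.

A mouse fold-change profile is mapped onto a human signature via a
gene-symbol map, restricted to the signature genes, and compared to fixed
per-subtype centroids (Proneural, Neural, Classical, Mesenchymal in the
canonical four-subtype scheme). Distances are 1 - Spearman correlation by
default (Pearson and Euclidean are selectable). Confidence comes from a
bootstrap null: the profile's fold-change values are resampled with
replacement onto the signature positions — deliberately breaking the
gene/centroid pairing so the null describes "no association" — and the
distance to each fixed centroid is recorded for each of B replicates.
The one-sided p-value is the add-one-corrected lower-tail probability
(small distance = similar), and assignment goes to the subtype with the
smallest observed/expected ("relative") distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GeneMap",
    "SubtypeResult",
    "CentroidSubtypeClassifier",
    "map_profile",
    "centroid_distance",
    "bootstrap_null",
    "simulation_test",
]

METRICS = ("spearman", "pearson", "euclidean")


@dataclass
class GeneMap:
    """Source→target gene-symbol map (e.g. mouse symbol → human symbol).

    ``policy`` resolves duplicate source symbols: ``"first"`` keeps the first
    pair, ``"drop"`` removes ambiguous sources entirely, ``"error"`` refuses.
    """

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs, policy: str = "first") -> "GeneMap":
        if policy not in ("first", "drop", "error"):
            raise ValueError(f"unknown collision policy {policy!r}")
        seen: dict[str, str] = {}
        ambiguous: set[str] = set()
        for source, target in pairs:
            if source in seen:
                if policy == "error" and seen[source] != target:
                    raise ValueError(f"duplicate source symbol {source!r}")
                if policy == "drop" and seen[source] != target:
                    ambiguous.add(source)
                continue
            seen[source] = target
        for source in ambiguous:
            del seen[source]
        return cls(seen)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class SubtypeResult:
    """Outcome of classifying one profile against a centroid set.

    ``table`` has one row per subtype: observed distance, expected (mean
    null) distance, relative distance observed/expected, add-one p-value and
    a flag for falling below the null's lower ``tail_level`` quantile.
    """

    table: pd.DataFrame
    assigned: str
    n_mapped_genes: int
    B: int
    tail_level: float
    seed: int | None = None
    metric: str = "spearman"
    n_redrawn: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "assigned": self.assigned,
            "n_mapped_genes": self.n_mapped_genes,
            "B": self.B,
            "tail_level": self.tail_level,
            "metric": self.metric,
            "seed": self.seed,
            "subtypes": self.table.to_dict(orient="index"),
        }


# ---------------------------------------------------------------------------
# mapping and distances
# ---------------------------------------------------------------------------


def _check_centroids(centroids: pd.DataFrame) -> None:
    if centroids.index.has_duplicates:
        raise ValueError("duplicate genes in centroid set")
    if centroids.shape[1] < 2:
        raise ValueError("need at least 2 subtype centroids")
    if centroids.isna().any().any():
        raise ValueError("centroid set contains missing values")


def map_profile(
    profile: pd.Series,
    gene_map: GeneMap | None,
    centroids: pd.DataFrame,
    min_mapped_fraction: float = 0.5,
) -> pd.Series:
    """Map a fold-change profile onto the signature genes, in centroid order.

    ``gene_map=None`` means symbols are already in the target namespace.
    When several source genes land on the same signature gene their fold
    changes are averaged. Raises if no signature gene is reachable; warns if
    fewer than ``min_mapped_fraction`` of the signature is covered.
    """
    _check_centroids(centroids)
    if gene_map is not None:
        if not len(gene_map):
            raise ValueError("gene map is empty")
        renamed = profile.rename(index=gene_map.mapping)
        renamed = renamed[renamed.index.isin(centroids.index)]
        mapped = renamed.groupby(level=0).mean()
    else:
        mapped = profile[profile.index.isin(centroids.index)]
    ordered = mapped.reindex([g for g in centroids.index if g in mapped.index])
    if ordered.empty:
        raise ValueError("no profile gene maps onto the centroid signature")
    fraction = len(ordered) / len(centroids.index)
    if fraction < min_mapped_fraction:
        warnings.warn(
            f"only {len(ordered)}/{len(centroids.index)} signature genes mapped "
            f"({fraction:.0%} < {min_mapped_fraction:.0%})",
            stacklevel=2,
        )
    return ordered


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=-1, method="average")


def _row_distances(rows: np.ndarray, centroid: np.ndarray, metric: str) -> np.ndarray:
    """Distance of each row of ``rows`` to ``centroid`` (vectorized)."""
    if metric == "euclidean":
        return np.linalg.norm(rows - centroid[None, :], axis=1)
    if metric == "spearman":
        rows = _rank_rows(rows)
        centroid = stats.rankdata(centroid)
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    cent_c = centroid - centroid.mean()
    denom = np.sqrt((rows_c**2).sum(axis=1) * (cent_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = rows_c @ cent_c / denom
    return 1.0 - corr


def centroid_distance(
    mapped: pd.Series, centroids: pd.DataFrame, metric: str = "spearman"
) -> pd.Series:
    """Per-subtype distance of a mapped profile to each centroid.

    Correlation metrics give ``1 - r`` in [0, 2]; ``euclidean`` gives the L2
    norm of the difference. Correlation metrics need >= 3 shared genes and
    nonzero variance on both sides.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    _check_centroids(centroids)
    sub = centroids.loc[mapped.index]
    values = mapped.to_numpy(dtype=float)
    if metric in ("spearman", "pearson"):
        if len(values) < 3:
            raise ValueError("correlation metrics need at least 3 shared genes")
        if np.ptp(values) == 0:
            raise ValueError("profile has zero variance under a correlation metric")
        for label in sub.columns:
            if np.ptp(sub[label].to_numpy()) == 0:
                raise ValueError(
                    f"centroid {label!r} has zero variance under a correlation metric"
                )
    out = {
        label: float(
            _row_distances(values[None, :], sub[label].to_numpy(dtype=float), metric)[0]
        )
        for label in sub.columns
    }
    return pd.Series(out, name="distance")


# ---------------------------------------------------------------------------
# bootstrap null
# ---------------------------------------------------------------------------


def bootstrap_null(
    mapped: pd.Series,
    centroids: pd.DataFrame,
    metric: str = "spearman",
    B: int = 1000,
    seed: int | None = None,
    scheme: str = "bootstrap",
    enumeration_cap: int = 100_000,
) -> tuple[dict[str, np.ndarray], pd.Series, int]:
    """Null distance distributions from resampled fold-change values.

    Each replicate resamples the profile's values (with replacement under
    ``scheme="bootstrap"``, without under ``scheme="permutation"``) and
    assigns them to the signature positions without preserving the gene
    pairing; centroids stay fixed, and the distance to each is recorded.
    Replicates that are constant under a correlation metric are redrawn
    (their count is returned). When ``n ** n <= enumeration_cap`` and the
    scheme is ``bootstrap``, sampling is replaced by exhaustive enumeration
    of all ``n**n`` equally likely value assignments.

    Returns ``(nulls, expected, n_redrawn)`` where ``nulls[subtype]`` is the
    replicate distance vector and ``expected`` its mean per subtype.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if scheme not in ("bootstrap", "permutation"):
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_centroids(centroids)
    values = mapped.to_numpy(dtype=float)
    n = len(values)
    sub = centroids.loc[mapped.index]

    exhaustive = scheme == "bootstrap" and n > 0 and n**n <= enumeration_cap
    n_redrawn = 0
    if exhaustive:
        assignments = np.array(
            list(itertools.product(range(n), repeat=n)), dtype=np.intp
        )
        rows = values[assignments]
        if metric in ("spearman", "pearson"):
            keep = np.ptp(rows, axis=1) > 0
            n_redrawn = int((~keep).sum())
            rows = rows[keep]
            if rows.shape[0] == 0:
                raise ValueError(
                    "every enumerated assignment is constant; "
                    "correlation metric undefined"
                )
    else:
        rng = np.random.default_rng(seed)
        rows = _draw_rows(rng, values, B, scheme)
        if metric in ("spearman", "pearson"):
            bad = np.ptp(rows, axis=1) == 0
            guard = 0
            while bad.any():
                n_redrawn += int(bad.sum())
                rows[bad] = _draw_rows(rng, values, int(bad.sum()), scheme)
                bad = np.ptp(rows, axis=1) == 0
                guard += 1
                if guard > 1000:
                    raise ValueError(
                        "profile values admit no non-constant resample; "
                        "correlation metric undefined"
                    )

    nulls = {
        label: _row_distances(rows, sub[label].to_numpy(dtype=float), metric)
        for label in sub.columns
    }
    expected = pd.Series({label: float(d.mean()) for label, d in nulls.items()})
    return nulls, expected, n_redrawn


def _draw_rows(rng, values: np.ndarray, count: int, scheme: str) -> np.ndarray:
    n = len(values)
    if scheme == "bootstrap":
        idx = rng.integers(0, n, size=(count, n))
        return values[idx]
    return rng.permuted(np.broadcast_to(values, (count, n)).copy(), axis=1)


# ---------------------------------------------------------------------------
# simulation test
# ---------------------------------------------------------------------------


def simulation_test(
    observed: pd.Series,
    nulls: dict[str, np.ndarray],
    tail_level: float = 0.05,
    pooled: bool = False,
    assignment: str = "relative",
) -> SubtypeResult:
    """One-sided simulation test: is the observed distance in the null's lower tail?

    Per subtype, ``p = (1 + #{null <= observed}) / (B + 1)`` (add-one
    corrected, so p >= 1/(B+1)); a subtype is significant when the observed
    distance falls below the null's lower ``tail_level`` quantile. The
    profile is assigned to the subtype minimizing the relative distance
    observed/expected (``assignment="raw"`` uses the raw distance); ties
    break by raw distance, then label order. ``pooled=True`` evaluates every
    subtype against the union of all subtype nulls.
    """
    if not 0 < tail_level < 1:
        raise ValueError(f"tail_level must be in (0, 1), got {tail_level}")
    if assignment not in ("relative", "raw"):
        raise ValueError(f"assignment must be 'relative' or 'raw', got {assignment!r}")
    if not nulls or any(len(v) == 0 for v in nulls.values()):
        raise ValueError("null distributions must be non-empty")
    labels = list(observed.index)
    pooled_null = np.concatenate([np.asarray(nulls[lab]) for lab in labels])
    rows = []
    for label in labels:
        null = pooled_null if pooled else np.asarray(nulls[label])
        B = len(null)
        obs = float(observed[label])
        p = (1 + int((null <= obs).sum())) / (B + 1)
        expected = float(null.mean())
        rows.append(
            {
                "subtype": label,
                "observed": obs,
                "expected": expected,
                "relative": obs / expected if expected > 0 else float("inf"),
                "p_value": p,
                "significant": obs < float(np.quantile(null, tail_level)),
            }
        )
    table = pd.DataFrame(rows).set_index("subtype")
    key = "relative" if assignment == "relative" else "observed"
    # stable three-level tie-break: key, then raw distance, then label order
    ordered = table.reset_index().sort_values(
        [key, "observed", "subtype"], kind="mergesort"
    )
    assigned = str(ordered["subtype"].iloc[0])
    B_used = len(pooled_null) if pooled else len(np.asarray(nulls[labels[0]]))
    return SubtypeResult(
        table=table,
        assigned=assigned,
        n_mapped_genes=len(observed) if observed.ndim else 0,
        B=B_used,
        tail_level=tail_level,
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class CentroidSubtypeClassifier(BaseEstimator):
    """Nearest-centroid subtype classifier with a bootstrap simulation test.

    Parameters
    ----------
    metric
        ``"spearman"`` (default; robust across platforms), ``"pearson"`` or
        ``"euclidean"``.
    B
        Bootstrap replicate count for the null (default 1000).
    tail_level
        Lower-tail level for the significance shading (default 0.05).
    scheme
        ``"bootstrap"`` (values resampled with replacement) or
        ``"permutation"``.
    assignment
        ``"relative"`` assigns by observed/expected distance, ``"raw"`` by
        observed distance alone.
    pooled_null
        Evaluate p-values against the pooled null across subtype-centroid
        pairs instead of per-subtype nulls.
    enumeration_cap
        Switch to exhaustive enumeration of all ``n**n`` assignments when
        feasible.
    random_state
        Seed for the bootstrap.
    """

    def __init__(
        self,
        metric: str = "spearman",
        B: int = 1000,
        tail_level: float = 0.05,
        scheme: str = "bootstrap",
        assignment: str = "relative",
        pooled_null: bool = False,
        enumeration_cap: int = 100_000,
        min_mapped_fraction: float = 0.5,
        random_state: int | None = None,
    ):
        self.metric = metric
        self.B = B
        self.tail_level = tail_level
        self.scheme = scheme
        self.assignment = assignment
        self.pooled_null = pooled_null
        self.enumeration_cap = enumeration_cap
        self.min_mapped_fraction = min_mapped_fraction
        self.random_state = random_state

    def fit(self, centroids: pd.DataFrame, y=None):
        """Store the signature-gene x subtype centroid matrix."""
        _check_centroids(centroids)
        self.centroids_ = centroids.copy()
        self.subtypes_ = list(centroids.columns)
        self.n_signature_genes_ = len(centroids.index)
        return self

    def classify(
        self, profile: pd.Series, gene_map: GeneMap | None = None
    ) -> SubtypeResult:
        """Full classification of one fold-change profile: distances, null, test."""
        self._check_fitted()
        mapped = map_profile(
            profile, gene_map, self.centroids_, self.min_mapped_fraction
        )
        observed = centroid_distance(mapped, self.centroids_, self.metric)
        nulls, expected, n_redrawn = bootstrap_null(
            mapped,
            self.centroids_,
            metric=self.metric,
            B=self.B,
            seed=self.random_state,
            scheme=self.scheme,
            enumeration_cap=self.enumeration_cap,
        )
        result = simulation_test(
            observed,
            nulls,
            tail_level=self.tail_level,
            pooled=self.pooled_null,
            assignment=self.assignment,
        )
        result.n_mapped_genes = len(mapped)
        result.seed = self.random_state
        result.metric = self.metric
        result.n_redrawn = n_redrawn
        return result

    def predict(self, X, gene_map: GeneMap | None = None):
        """Assigned subtype label(s) for one profile (Series) or several (DataFrame rows)."""
        self._check_fitted()
        if isinstance(X, pd.Series):
            return self.classify(X, gene_map).assigned
        frame = pd.DataFrame(X)
        return np.array(
            [self.classify(frame.loc[idx], gene_map).assigned for idx in frame.index]
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "centroids_"):
            raise ValueError("classifier is not fitted; call fit(centroids) first")
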