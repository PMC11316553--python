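"""Same-strain ANI null distribution: pooling, bootstrap, ANOVA, KDE,
empirical P-values, and the three-way strain call.

The model: ANI values between assemblies rebuilt from independent read
subsamples of the *same* isolate capture pure sequencing/assembly noise.
Pooled per species and enlarged by a bootstrap (with replacement, default
10,000 draws), they form an empirical null for the hypothesis "these two
genomes are the same strain".  An observed ANI between two genomes is
projected onto this distribution; the alternative is one-sided (a truly
different strain is an outlier on the left tail), so the empirical P-value
is the left-tail ECDF probability P = #{null <= observed}/n.  Calls:

* P <  ``p_low``  (default 0.05)  -> "different"
* P >= ``p_high`` (default 0.95)  -> "identical"
* otherwise                        -> "related"

P-values come from the plain ECDF of the bootstrap sample; the Gaussian
KDE (Silverman bandwidth) is fit for visualization, with an optional
KDE-integrated tail probability behind ``p_from="kde"``.  A one-way ANOVA
of pooled ANI by strain is reported (never used as a gate): a significant
strain effect is evidence that strain-level diversity is represented in
the pool, and a warning is logged otherwise.  Each species gets its own
null, built independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

CATEGORIES = ("different", "related", "identical")


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA of ANI grouped by strain."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass
class KDEModel:
    """Gaussian KDE of the pooled null, for plotting and optional tail areas."""

    bandwidth: float
    support: np.ndarray
    density: np.ndarray
    kernel: str = "gaussian"
    _kde: stats.gaussian_kde | None = field(default=None, repr=False)

    def evaluate(self, x) -> np.ndarray:
        return self._kde(np.atleast_1d(np.asarray(x, dtype=float)))

    def left_tail(self, x: float) -> float:
        """Integrated density over (-inf, x]."""
        return float(np.clip(self._kde.integrate_box_1d(-np.inf, x), 0.0, 1.0))


@dataclass
class StrainCall:
    """One compared genome pair with its observed ANI, P-value and category."""

    genome_a: str
    genome_b: str
    observed_ani: float
    empirical_p: float
    category: str


@dataclass
class PooledNull:
    """Per-species same-strain ANI pool with bootstrap sample and KDE."""

    species: str
    values: list[tuple[str, float]]
    bootstrap_sample: np.ndarray | None = None
    kde: KDEModel | None = None
    anova: AnovaResult | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("pooled null requires at least one ANI value")
        for _, v in self.values:
            if not (0.0 < v <= 100.0):
                raise ValueError(f"pooled ANI {v} outside (0, 100]")

    @property
    def ani_values(self) -> np.ndarray:
        return np.array([v for _, v in self.values], dtype=float)

    @property
    def strain_labels(self) -> list[str]:
        return [s for s, _ in self.values]

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "values": [[s, v] for s, v in self.values],
            "bootstrap_sample": (None if self.bootstrap_sample is None
                                 else self.bootstrap_sample.tolist()),
            "anova": (None if self.anova is None else vars(self.anova)),
            "kde_bandwidth": None if self.kde is None else self.kde.bandwidth,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path) -> "PooledNull":
        with open(path) as handle:
            payload = json.load(handle)
        null = cls(species=payload["species"],
                   values=[(s, float(v)) for s, v in payload["values"]])
        if payload.get("bootstrap_sample") is not None:
            null.bootstrap_sample = np.array(payload["bootstrap_sample"])
        if payload.get("anova") is not None:
            null.anova = AnovaResult(**payload["anova"])
        vals = null.ani_values
        if len(np.unique(vals)) >= 2:
            null.kde = fit_kde(vals)
        return null


# ---------------------------------------------------------------------------
# sklearn-style estimator


class StrainNullClassifier(BaseEstimator):
    """Three-way strain-identity classifier fit on a same-strain ANI null.

    ``fit`` takes the pooled same-strain ANI values of one species (shape
    ``(n,)`` or ``(n, 1)``, percent scale) with optional per-value strain
    labels ``y``; it draws the bootstrap sample, fits the KDE, and runs the
    strain-effect ANOVA when labels allow.  ``predict`` maps observed ANI
    values to ``{"different", "related", "identical"}`` via the left-tail
    empirical P-value, available directly from :meth:`predict_p`.

    Parameters
    ----------
    n_bootstrap : int, default 10000
        Size of the bootstrap sample drawn with replacement from the pool.
    p_low, p_high : float, defaults 0.05 and 0.95
        Call thresholds: P < p_low is "different", P >= p_high "identical".
    p_from : {"ecdf", "kde"}, default "ecdf"
        Whether P-values are plain ECDF probabilities of the bootstrap
        sample or integrated KDE left tails.
    bandwidth : str or float, default "silverman"
        KDE bandwidth rule (passed to :class:`scipy.stats.gaussian_kde`).
    random_state : int or None
        Seed for the bootstrap draw.
    """

    def __init__(self, n_bootstrap: int = 10000, p_low: float = 0.05,
                 p_high: float = 0.95, p_from: str = "ecdf",
                 bandwidth="silverman", random_state: int | None = None):
        self.n_bootstrap = n_bootstrap
        self.p_low = p_low
        self.p_high = p_high
        self.p_from = p_from
        self.bandwidth = bandwidth
        self.random_state = random_state

    def _validate_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1-d array of ANI percentages")
        if np.any(~np.isfinite(X)) or np.any(X <= 0) or np.any(X > 100):
            raise ValueError("ANI values must be finite and in (0, 100]")
        return X

    def fit(self, X, y=None) -> "StrainNullClassifier":
        _validate_thresholds(self.p_low, self.p_high)
        if self.p_from not in ("ecdf", "kde"):
            raise ValueError("p_from must be 'ecdf' or 'kde'")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        X = self._validate_x(X)
        if len(X) == 0:
            raise ValueError("cannot fit a null on an empty pool")
        self.null_values_ = X
        self.strain_labels_ = None if y is None else np.asarray(y)
        self.n_features_in_ = 1

        self.bootstrap_sample_ = bootstrap_sample(
            X, B=self.n_bootstrap, seed=self.random_state)
        self._sorted_bootstrap_ = np.sort(self.bootstrap_sample_)

        if len(np.unique(X)) >= 2:
            self.kde_ = fit_kde(X, bandwidth_rule=self.bandwidth)
        else:
            self.kde_ = None
            if self.p_from == "kde":
                raise ValueError("p_from='kde' requires >= 2 distinct null values")
            logger.warning("all pooled ANI values identical; KDE not fit")

        self.anova_ = None
        if self.strain_labels_ is not None:
            groups = _group_values(X, self.strain_labels_)
            if (len(groups) >= 2 and all(len(g) >= 2 for g in groups.values())
                    and np.ptp(X) > 0):
                self.anova_ = oneway_anova(list(groups.values()))
                if self.anova_.p_value >= 0.05:
                    logger.warning(
                        "strain-effect ANOVA p=%.3f >= 0.05: the pool may "
                        "under-represent strain diversity", self.anova_.p_value)
            else:
                logger.info("ANOVA undefined for this pool (needs >= 2 strains "
                            "with >= 2 values each and non-zero variance)")
        return self

    def predict_p(self, X) -> np.ndarray:
        """Left-tail empirical P-value for each observed ANI."""
        check_is_fitted(self, "bootstrap_sample_")
        X = self._validate_x(X)
        if self.p_from == "kde":
            return np.array([self.kde_.left_tail(x) for x in X])
        counts = np.searchsorted(self._sorted_bootstrap_, X, side="right")
        return counts / len(self._sorted_bootstrap_)

    def predict(self, X) -> np.ndarray:
        p = self.predict_p(X)
        return np.array([classify_pair(pi, self.p_low, self.p_high) for pi in p])

    def to_pooled_null(self, species: str) -> PooledNull:
        check_is_fitted(self, "bootstrap_sample_")
        labels = (self.strain_labels_ if self.strain_labels_ is not None
                  else ["?"] * len(self.null_values_))
        return PooledNull(species=species,
                          values=list(zip(map(str, labels),
                                          self.null_values_.tolist())),
                          bootstrap_sample=self.bootstrap_sample_,
                          kde=self.kde_, anova=self.anova_)


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers / primitives)


def _validate_thresholds(p_low: float, p_high: float) -> None:
    if not (0.0 <= p_low < p_high <= 1.0):
        raise ValueError(f"need 0 <= p_low < p_high <= 1, got ({p_low}, {p_high})")


def _group_values(values: np.ndarray, labels) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        groups.setdefault(str(lab), []).append(float(v))
    return {k: np.array(v) for k, v in groups.items()}


def pool_ani(per_strain: dict[str, list[float]], species: str = "") -> PooledNull:
    """Concatenate per-strain same-strain ANI values, keeping labels."""
    if not per_strain or any(len(v) == 0 for v in per_strain.values()):
        raise ValueError("pool_ani requires >= 1 strain, each with >= 1 value")
    values = [(strain, float(v)) for strain, vals in per_strain.items()
              for v in vals]
    return PooledNull(species=species, values=values)


def bootstrap_sample(values, B: int = 10000, seed: int | None = None) -> np.ndarray:
    """Draw ``B`` values with replacement from ``values`` (seeded)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(values, size=B, replace=True)


def oneway_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA over ``groups`` of ANI values."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two strain groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each strain group needs at least two values")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ValueError("ANOVA undefined: zero total variance in the pool")
    f, p = stats.f_oneway(*groups)
    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       df_between=len(groups) - 1,
                       df_within=len(allv) - len(groups))


def strain_anova(pool: PooledNull) -> AnovaResult:
    """ANOVA of a pooled null's ANI values grouped by strain label."""
    groups = _group_values(pool.ani_values, pool.strain_labels)
    return oneway_anova(list(groups.values()))


def fit_kde(values, bandwidth_rule="silverman") -> KDEModel:
    """Gaussian KDE of the pool (Silverman bandwidth unless overridden)."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("KDE requires >= 2 distinct values; "
                         "override the bandwidth for degenerate pools")
    kde = stats.gaussian_kde(values, bw_method=bandwidth_rule)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    lo = values.min() - 5 * bandwidth
    hi = values.max() + 5 * bandwidth
    support = np.linspace(lo, hi, 2048)
    return KDEModel(bandwidth=bandwidth, support=support,
                    density=kde(support), _kde=kde)


def empirical_p(null_values, observed_ani: float) -> float:
    """Left-tail ECDF probability: #{null <= observed}/n.

    Small ANI (left-tail outlier) gives a small P; an observed value at or
    above the null maximum gives P = 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) == 0:
        raise ValueError("empirical_p requires a non-empty null sample")
    return float(np.count_nonzero(null_values <= observed_ani) / len(null_values))


def classify_pair(p: float, p_low: float = 0.05, p_high: float = 0.95) -> str:
    """Three-way call from an empirical P-value.

    P < ``p_low`` -> "different"; P >= ``p_high`` -> "identical"; otherwise
    "related".  Ties follow the operational rule: exactly ``p_high`` is
    "identical", exactly ``p_low`` is "related".
    """
    _validate_thresholds(p_low, p_high)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"empirical P {p} outside [0, 1]")
    if p < p_low:
        return "different"
    if p >= p_high:
        return "identical"
    return "related"
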