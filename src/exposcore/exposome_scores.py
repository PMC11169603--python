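"""Exposome processing: binary risk indicators, correlation structure and
cumulative Poly-Environmental Risk Scores (PERS).

The pipeline mirrors standard exposome practice: heterogeneous raw exposures
are dichotomised into risk indicators (1 = risk present), near-duplicate
measurements (|r| > 0.8) are collapsed to one representative, the retained
indicators are characterised by their tetrachoric correlation matrix and
Ward clustering, assigned to three interpretable domains (social/household,
lifestyle/behaviour, wider environment & health), and summed with equal
weights into cumulative domain scores plus a total score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
import yaml
from scipy.spatial.distance import squareform
from scipy.stats import multivariate_normal, norm

DOMAINS = ("Soc", "Life", "Env")

__all__ = [
    "DOMAINS",
    "ExposureSpec",
    "ExposureCatalogue",
    "DomainAssignment",
    "default_catalogue",
    "binarize",
    "binarize_matrix",
    "redundancy_filter",
    "tetrachoric",
    "tetrachoric_matrix",
    "cluster_exposures",
    "assign_domains",
    "assign_domains_from_catalogue",
    "compute_pers",
    "known_group_validity",
]


@dataclass(frozen=True)
class ExposureSpec:
    """Declarative description of one raw exposure column.

    ``kind`` is ``"categorical"`` (already coded so that >= 1 means the risk
    is present) or ``"numeric"`` (dichotomised at the quartile of the risk
    tail).  ``risk_direction`` states which tail of a numeric exposure is the
    risk: ``"low_is_risk"`` (e.g. sleep hours, greenness) flags the lowest
    quartile, ``"high_is_risk"`` (e.g. NO2, media exposure) the highest.
    ``domain`` is the nominal domain; ``domain_override`` records an explicit
    interpretability assignment that takes precedence over clustering.
    """

    name: str
    kind: str
    domain: str
    risk_direction: str | None = None
    redundancy_group: str | None = None
    domain_override: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"{self.name}: kind must be categorical|numeric, got {self.kind!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"{self.name}: domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.kind == "numeric" and self.risk_direction not in ("low_is_risk", "high_is_risk"):
            raise ValueError(f"{self.name}: numeric exposures need a risk_direction")
        if self.domain_override is not None and self.domain_override not in DOMAINS:
            raise ValueError(f"{self.name}: invalid domain_override {self.domain_override!r}")


class ExposureCatalogue:
    """Ordered collection of :class:`ExposureSpec` driving binarization,
    redundancy grouping and domain assignment."""

    def __init__(self, specs: Iterable[ExposureSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("exposure names must be unique")
        self._specs = {s.name: s for s in specs}

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self):
        return iter(self._specs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ExposureSpec:
        return self._specs[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def to_yaml(self, path) -> None:
        payload = [
            {k: v for k, v in vars(s).items() if v is not None} for s in self
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExposureCatalogue":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(ExposureSpec(**entry) for entry in payload)


def default_catalogue() -> ExposureCatalogue:
    """The shipped 18-exposure catalogue: six social/household, six
    lifestyle/behaviour and six wider-environment & health indicators.

    Five entries carry explicit domain overrides reflecting interpretability
    decisions (outdoor access grouped with behaviour; living alone and
    caregiving with social factors; chronic disease and COVID-19 with the
    wider environment) rather than their data-driven cluster.
    """
    c, n = "categorical", "numeric"
    return ExposureCatalogue(
        [
            ExposureSpec("loneliness", c, "Soc"),
            ExposureSpec("household_conflicts", c, "Soc"),
            ExposureSpec("caregiving", c, "Soc", domain_override="Soc"),
            ExposureSpec("living_alone", c, "Soc", domain_override="Soc"),
            ExposureSpec("unemployed", c, "Soc"),
            ExposureSpec("rent_food_struggle", c, "Soc"),
            ExposureSpec("physical_activity", n, "Life", risk_direction="low_is_risk"),
            ExposureSpec("alcohol_intake", n, "Life", risk_direction="high_is_risk"),
            ExposureSpec("current_smoker", c, "Life"),
            ExposureSpec("sleep_hours", n, "Life", risk_direction="low_is_risk"),
            ExposureSpec("media_exposure", n, "Life", risk_direction="high_is_risk"),
            ExposureSpec("no_outdoor_access", c, "Life", domain_override="Life"),
            ExposureSpec("low_natural_views", c, "Env"),
            ExposureSpec("urbanization", n, "Env", risk_direction="high_is_risk"),
            ExposureSpec("ndvi", n, "Env", risk_direction="low_is_risk"),
            ExposureSpec("no2", n, "Env", risk_direction="high_is_risk"),
            ExposureSpec("chronic_disease", c, "Env", domain_override="Env"),
            ExposureSpec("covid19", c, "Env", domain_override="Env"),
        ]
    )


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize(values, spec: ExposureSpec) -> np.ndarray:
    """Dichotomise one exposure column into a 0/1 risk indicator.

    Categorical: risk present iff value >= 1.  Numeric: risk present in the
    quartile of the risk tail (<= empirical 25th percentile when low values
    are the risk, >= 75th percentile when high values are), computed with the
    linear-interpolation quantile; ties at the cut-off are flagged as risk.
    A constant numeric column carries no information: all zeros, with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"{spec.name}: missing values must be excluded upstream")
    if spec.kind == "categorical":
        return (x >= 1).astype(np.int8)
    if x.min() == x.max():
        warnings.warn(f"{spec.name}: constant numeric column, no risk flags set", stacklevel=2)
        return np.zeros(len(x), dtype=np.int8)
    if spec.risk_direction == "low_is_risk":
        return (x <= np.quantile(x, 0.25)).astype(np.int8)
    return (x >= np.quantile(x, 0.75)).astype(np.int8)


def binarize_matrix(exposures: pd.DataFrame, catalogue: ExposureCatalogue) -> pd.DataFrame:
    """Apply :func:`binarize` to every catalogue exposure present in
    ``exposures``; returns the participants x exposures 0/1 matrix."""
    cols = {}
    for spec in catalogue:
        if spec.name not in exposures.columns:
            raise KeyError(f"exposure column {spec.name!r} missing from input table")
        cols[spec.name] = binarize(exposures[spec.name].to_numpy(), spec)
    return pd.DataFrame(cols, index=exposures.index)


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

def redundancy_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.8,
    catalogue: ExposureCatalogue | None = None,
):
    """Collapse near-duplicate exposures (|Pearson r| > ``threshold``).

    Exposures are partitioned into connected components of the graph with an
    edge wherever |r| > threshold; one representative is retained per
    component — the first in catalogue/column order, unless a component
    member's ``redundancy_group`` designates a preferred representative.

    Returns ``(retained, groups, max_residual_r)`` where ``groups`` lists the
    multi-member components and ``max_residual_r`` is the largest remaining
    absolute pairwise correlation among retained exposures.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 exposures")
    order = matrix.columns.tolist()
    if catalogue is not None:
        in_cat = [c for c in catalogue.names if c in order]
        order = in_cat + [c for c in order if c not in in_cat]

    with np.errstate(invalid="ignore"):
        corr = matrix[order].corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    # union-find over the thresholded graph
    parent = list(range(len(order)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            if abs(corr[i, j]) > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    components: dict[int, list[str]] = {}
    for i, name in enumerate(order):
        components.setdefault(find(i), []).append(name)

    retained, groups = [], []
    for root in sorted(components):
        members = components[root]
        rep = members[0]
        if catalogue is not None:
            preferred = [
                m for m in members
                if m in catalogue and catalogue[m].redundancy_group == m
            ]
            if preferred:
                rep = preferred[0]
        retained.append(rep)
        if len(members) > 1:
            groups.append({"representative": rep, "members": members})

    idx = [order.index(r) for r in retained]
    sub = np.abs(corr[np.ix_(idx, idx)]).copy()
    np.fill_diagonal(sub, 0.0)
    max_residual = float(sub.max()) if len(idx) > 1 else 0.0
    return retained, groups, max_residual


# ---------------------------------------------------------------------------
# Tetrachoric correlation
# ---------------------------------------------------------------------------

def _bvn_cdf(h: float, k: float, r: float) -> float:
    cov = np.array([[1.0, r], [r, 1.0]])
    return float(multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf([h, k]))


def tetrachoric(x, y) -> float:
    """Maximum-likelihood tetrachoric correlation of two binary vectors.

    Assumes a latent bivariate-normal pair dichotomised at thresholds set by
    the margins; solves Phi2(h, k; r) = p11 for r.  Empty 2x2 cells receive a
    +0.5 continuity correction; the estimate is clamped to [-0.999, 0.999].
    A degenerate margin (all 0 or all 1) is undefined and returns NaN.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 10:
        raise ValueError("need n >= 10")
    for v in (x, y):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("inputs must be binary 0/1")
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    return tetrachoric_from_table(np.array([[n00, n01], [n10, n11]]))


def tetrachoric_from_table(table: np.ndarray) -> float:
    """Tetrachoric r from a 2x2 table ``[[n00, n01], [n10, n11]]``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan")  # margin degenerate: latent threshold at +-inf
    if (t == 0).any():
        t = t + 0.5
    n = t.sum()
    p1x = (t[1, 0] + t[1, 1]) / n  # P(x = 1)
    p1y = (t[0, 1] + t[1, 1]) / n  # P(y = 1)
    p11 = t[1, 1] / n
    h = norm.ppf(1 - p1x)
    k = norm.ppf(1 - p1y)

    def f(r: float) -> float:
        # upper-orthant probability via inclusion-exclusion on the CDF
        upper = 1.0 - norm.cdf(h) - norm.cdf(k) + _bvn_cdf(h, k, r)
        return upper - p11

    lo, hi = -0.999, 0.999
    flo, fhi = f(lo), f(hi)
    if flo >= 0:
        return -0.999
    if fhi <= 0:
        return 0.999
    from scipy.optimize import brentq

    r = brentq(f, lo, hi, xtol=1e-10)
    return float(np.clip(r, -0.999, 0.999))


def tetrachoric_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise tetrachoric correlation matrix of a binary exposure matrix.
    Undefined pairs (degenerate margins) are NaN."""
    cols = matrix.columns
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    arrs = {c: matrix[c].to_numpy() for c in cols}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = tetrachoric(arrs[a], arrs[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# Clustering and domain assignment
# ---------------------------------------------------------------------------

def cluster_exposures(corr: pd.DataFrame, k: int = 3):
    """Ward hierarchical clustering of exposures on distance d = 1 - r.

    Missing correlations are imputed as 0 with a warning.  Returns
    ``(linkage, labels)`` where ``labels`` maps exposure name -> cluster id
    (1..k) from the k-cluster cut.
    """
    c = corr.to_numpy(dtype=float).copy()
    if c.shape[0] != c.shape[1] or not np.allclose(np.diag(c), 1.0):
        raise ValueError("correlation matrix must be square with unit diagonal")
    if c.shape[0] < k:
        raise ValueError(f"need at least k={k} exposures, got {c.shape[0]}")
    if np.isnan(c).any():
        warnings.warn("missing correlations imputed as 0 before clustering", stacklevel=2)
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 1.0)
    c = (c + c.T) / 2
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = sch.linkage(squareform(dist, checks=False), method="ward")
    flat = sch.fcluster(linkage, t=k, criterion="maxclust")
    labels = dict(zip(corr.columns, (int(v) for v in flat)))
    return linkage, labels


@dataclass
class DomainAssignment:
    """Exposure -> domain map with provenance (``"override"`` for explicit
    interpretability assignments, ``"cluster"`` for majority-vote ones)."""

    domain: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def members(self, domain: str) -> list[str]:
        return [e for e, d in self.domain.items() if d == domain]


def assign_domains(labels: Mapping[str, int], catalogue: ExposureCatalogue) -> DomainAssignment:
    """Assign each clustered exposure to a domain.

    An explicit ``domain_override`` wins; otherwise the exposure takes the
    majority nominal domain of its cluster (ties broken by domain order
    Soc, Life, Env).
    """
    domain: dict[str, str] = {}
    provenance: dict[str, str] = {}
    cluster_members: dict[int, list[str]] = {}
    for name, lab in labels.items():
        cluster_members.setdefault(lab, []).append(name)

    for name in labels:
        if name not in catalogue:
            raise KeyError(f"exposure {name!r} has neither override nor catalogue entry")
        spec = catalogue[name]
        if spec.domain_override is not None:
            domain[name] = spec.domain_override
            provenance[name] = "override"
            continue
        peers = cluster_members[labels[name]]
        counts = {d: 0 for d in DOMAINS}
        for p in peers:
            if p in catalogue:
                counts[catalogue[p].domain] += 1
        domain[name] = max(DOMAINS, key=lambda d: counts[d])
        provenance[name] = "cluster"
    return DomainAssignment(domain, provenance)


def assign_domains_from_catalogue(catalogue: ExposureCatalogue) -> DomainAssignment:
    """Domain assignment straight from the catalogue (override when present,
    else the nominal domain) — the path used when the data-driven clustering
    step is not rerun."""
    domain, provenance = {}, {}
    for spec in catalogue:
        if spec.domain_override is not None:
            domain[spec.name] = spec.domain_override
            provenance[spec.name] = "override"
        else:
            domain[spec.name] = spec.domain
            provenance[spec.name] = "cluster"
    return DomainAssignment(domain, provenance)


# ---------------------------------------------------------------------------
# PERS
# ---------------------------------------------------------------------------

def compute_pers(matrix: pd.DataFrame, domains: DomainAssignment) -> pd.DataFrame:
    """Cumulative equal-weight risk scores per participant.

    Each domain score is the unweighted sum of its binary indicators;
    ``pers_total`` sums all indicators, so it equals the sum of the three
    domain scores by construction.
    """
    unknown = [c for c in matrix.columns if c not in domains.domain]
    if unknown:
        raise KeyError(f"matrix columns without domain assignment: {unknown}")
    out = pd.DataFrame(index=matrix.index)
    for d in DOMAINS:
        cols = [c for c in matrix.columns if domains.domain[c] == d]
        out[f"pers_{d.lower()}"] = matrix[cols].sum(axis=1).astype(int) if cols else 0
    out["pers_total"] = out[[f"pers_{d.lower()}" for d in DOMAINS]].sum(axis=1)
    return out


def known_group_validity(pers, criterion, sex):
    """Known-group validity: OLS of an external criterion on a PERS column,
    adjusted for sex.  Returns ``(slope, (ci_low, ci_high), p)``."""
    df = pd.DataFrame({"pers": np.asarray(pers, dtype=float),
                       "criterion": np.asarray(criterion, dtype=float),
                       "sex": np.asarray(sex, dtype=float)})
    if df.isna().any().any():
        raise ValueError("complete cases required")
    X = sm.add_constant(df[["pers", "sex"]])
    fit = sm.OLS(df["criterion"], X).fit()
    ci = fit.conf_int().loc["pers"]
    return float(fit.params["pers"]), (float(ci[0]), float(ci[1])), float(fit.pvalues["pers"])
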