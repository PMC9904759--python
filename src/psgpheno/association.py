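"""Normalization to wild-type means and covariate-phenotype fits.

Two bespoke fits relate molecular covariates to phenotypes:

* a one-phase exponential decay ``Y = a·e^(−kX) + b`` (protein level vs
  antisense-transcript level), fitted by bounded nonlinear least squares
  with multi-start initialization;
* ordinary least-squares linear regression ``Y = aX + b`` (normalized
  phenotype vs protein level) with the conventional two-sided slope-zero
  test.

Phenotypes are normalized by the mean of the wild-type control group, so
that group's mean normalized value is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Default reference group key: wild-type animals given the control compound.
WT_CONTROL = ("WT", "control")


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or does not converge."""


def normalize_to_wt(
    values_by_group: Mapping, reference=WT_CONTROL
) -> pd.DataFrame:
    """Divide every value by the reference (WT-control) group mean.

    ``values_by_group`` maps group label → array of raw values.  Returns a
    long frame with columns ``group``, ``raw_value``, ``normalized_value``
    and ``normalizer``.  The reference group's mean normalized value is 1 by
    construction; the operation is idempotent and invariant to a common
    scale factor on the raw values.
    """
    if reference not in values_by_group:
        raise FitError(f"reference group {reference!r} missing")
    ref = np.asarray(values_by_group[reference], dtype=float)
    if ref.size == 0:
        raise FitError(f"reference group {reference!r} is empty")
    normalizer = float(np.mean(ref))
    if normalizer <= 0:
        raise FitError(
            f"reference group mean must be positive (got {normalizer})"
        )
    rows = []
    for group, values in values_by_group.items():
        for v in np.asarray(values, dtype=float):
            rows.append({
                "group": group,
                "raw_value": v,
                "normalized_value": v / normalizer,
                "normalizer": normalizer,
            })
    return pd.DataFrame(rows)


@dataclass
class ExpDecayFit:
    """One-phase exponential decay fit ``Y = a·e^(−kX) + b`` with k ≥ 0."""

    a: float
    k: float
    b: float
    r_squared: float
    identifiable: bool = True
    message: str = ""

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(-self.k * x) + self.b


def _exp_model(x, a, k, b):
    return a * np.exp(-k * x) + b


def fit_exp_decay(x, y, n_restarts: int = 5, seed: int = 0) -> ExpDecayFit:
    """Fit ``Y = a·e^(−kX) + b`` by nonlinear least squares with k ≥ 0.

    Initialization: ``b0 = min(y)``, ``a0 = max(y) − b0``, ``k0`` from a
    log-linearization of ``y − b0``; plus jittered restarts, keeping the
    solution with the smallest residual sum of squares.  When the fitted
    decay is effectively flat, the (a, b) split is not identifiable and the
    fit is flagged accordingly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise FitError("x and y must have equal length")
    if len(x) < 4:
        raise FitError(f"need at least 4 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("x values are constant; decay rate not estimable")

    b0 = float(np.min(y))
    a0 = float(np.max(y) - b0)
    resid = y - b0 + 1e-12
    pos = resid > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope = np.polyfit(x[pos], np.log(resid[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(np.ptp(x), 1e-6)

    rng = np.random.default_rng(seed)
    best = None
    starts = [(a0 or 1.0, k0, b0)]
    for _ in range(n_restarts):
        starts.append((
            (a0 or 1.0) * rng.uniform(0.5, 2.0),
            k0 * rng.uniform(0.3, 3.0),
            b0 + rng.normal(0, 0.1 * (abs(a0) + 1e-6)),
        ))
    errors = []
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _exp_model, x, y, p0=p0,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        sse = float(np.sum((y - _exp_model(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError(
            "exponential-decay fit failed for all starts: " + "; ".join(errors)
        )
    sse, (a, k, b) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    # flat decay: a and b only enter through a+b, the split is arbitrary
    decay_span = abs(a) * abs(np.exp(-k * x.min()) - np.exp(-k * x.max()))
    y_scale = max(np.ptp(y), abs(y.mean()), 1e-12)
    identifiable = decay_span > 1e-6 * y_scale
    msg = "" if identifiable else (
        "fit is effectively constant: (a, b) split not identifiable, "
        "only a+b is determined"
    )
    return ExpDecayFit(a=float(a), k=float(k), b=float(b), r_squared=r2,
                       identifiable=identifiable, message=msg)


@dataclass
class LinearFit:
    """OLS fit ``Y = aX + b`` with the two-sided slope-zero test."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    stderr: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares with the conventional slope t-test.

    ``p_slope`` is the two-sided probability of the observed slope under
    the null of zero slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise FitError("x and y must have equal length")
    if len(x) < 3:
        raise FitError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("x values are constant; slope not estimable")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
    )


def phenotype_protein_table(
    manifest: pd.DataFrame,
    phenotypes: pd.DataFrame,
    reference_query: str = "genotype == 'WT' and treatment == 'control'",
) -> pd.DataFrame:
    """Join covariates with phenotypes and normalize to the WT-control mean.

    ``manifest`` must carry ``animal_id``, ``genotype``, ``treatment`` and
    ``protein_level``; ``phenotypes`` one row per animal with ``animal_id``
    plus one column per phenotype.  Returns a long frame (one row per
    animal × phenotype) with ``normalized_value`` scaled so the WT-control
    group mean is 1 per phenotype — ready for :func:`fit_linear` against
    ``protein_level``.
    """
    required = {"animal_id", "genotype", "treatment", "protein_level"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise FitError(f"manifest missing columns {sorted(missing_cols)}")
    if manifest["protein_level"].isna().any():
        bad = manifest.loc[manifest["protein_level"].isna(), "animal_id"].tolist()
        raise FitError(f"missing protein_level covariate for animals {bad}")
    merged = manifest.merge(phenotypes, on="animal_id", how="left", validate="1:1")
    pheno_cols = [c for c in phenotypes.columns if c != "animal_id"]
    for col in pheno_cols:
        if merged[col].isna().any():
            bad = merged.loc[merged[col].isna(), "animal_id"].tolist()
            raise FitError(f"missing phenotype {col!r} for animals {bad}")
    ref = merged.query(reference_query)
    if ref.empty:
        raise FitError(f"no reference animals matching {reference_query!r}")
    rows = []
    for col in pheno_cols:
        normalizer = float(ref[col].mean())
        if normalizer == 0:
            raise FitError(f"zero WT-control mean for phenotype {col!r}")
        for _, r in merged.iterrows():
            rows.append({
                "animal_id": r["animal_id"],
                "genotype": r["genotype"],
                "treatment": r["treatment"],
                "protein_level": r["protein_level"],
                "phenotype": col,
                "raw_value": r[col],
                "normalized_value": r[col] / normalizer,
            })
    return pd.DataFrame(rows)


def fit_all_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`fit_linear` of normalized value on protein level per phenotype."""
    rows = []
    for pheno, grp in table.groupby("phenotype", sort=False):
        fit = fit_linear(grp["protein_level"], grp["normalized_value"])
        rows.append({
            "phenotype": pheno,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_slope": fit.p_slope,
            "n": fit.n,
        })
    return pd.DataFrame(rows)
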