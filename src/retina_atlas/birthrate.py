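"""Per-class birth-rate curves over developmental age.

The estimator is a parametric Gaussian fit by method of moments: within each
group (major class, or inferred fate group) the curve is
``proportion * Normal(t; mu, sigma)`` with mu/sigma the sample mean and
standard deviation of member cells' ages, and proportion the group's share
among the (optionally downsampled) cells of the same location.  Each curve
therefore integrates analytically to its group's proportion, and the
proportions sum to 1 per location.

To counteract sample-size variation, cells are downsampled per sample to at
most ``n_downsample`` cells, without replacement; smaller samples are used in
full.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclasses.dataclass
class BirthCurve:
    group: str
    location: str
    mu: float
    sigma: float
    proportion: float

    def curve(self, t):
        """Scaled Gaussian density; integrates to ``proportion``."""
        return self.proportion * norm.pdf(np.asarray(t, dtype=float), self.mu, self.sigma)


def _downsample(cells: pd.DataFrame, n_downsample: int, seed) -> pd.DataFrame:
    if "sample_id" not in cells.columns:
        groups = [cells]
    else:
        groups = [g for _, g in cells.groupby("sample_id", sort=True)]
    rng = np.random.default_rng(seed)
    kept = []
    for g in groups:
        if len(g) > n_downsample:
            kept.append(g.sample(n=n_downsample, replace=False, random_state=rng))
        else:
            kept.append(g)
    return pd.concat(kept)


def estimate_birth_curves(
    cells: pd.DataFrame,
    group_col: str = "major_class",
    location: str | None = None,
    n_downsample: int = 20000,
    seed: int | None = None,
) -> list[BirthCurve]:
    """Fit one scaled-Gaussian birth curve per group.

    ``location`` restricts to macula or periphery after downsampling; groups
    with fewer than 2 cells (or zero age variance) are omitted with a
    warning.  Proportions are shares of the downsampled cells of the same
    location, so the curve integrals sum to 1.
    """
    if group_col not in cells.columns:
        raise KeyError(f"cells table has no column {group_col!r}")
    sub = _downsample(cells, n_downsample, seed)
    if location is not None:
        sub = sub[sub["location"] == location]
        if sub.empty:
            raise ValueError(f"no cells at location {location!r}")
    loc_label = location if location is not None else "all"
    # cells with an empty/missing group label (e.g. undetermined fate) are
    # excluded from the denominator
    labels = sub[group_col].astype(str)
    valid = labels.notna() & (labels != "") & (labels != "undetermined")
    sub = sub[valid]
    n_total = len(sub)
    curves = []
    for group, g in sorted(sub.groupby(group_col, sort=True)):
        ages = g["age_days"].to_numpy(dtype=float)
        if len(ages) < 2:
            warnings.warn(f"group {group!r}: fewer than 2 cells, curve omitted")
            continue
        sigma = float(ages.std(ddof=1))
        if sigma == 0:
            warnings.warn(f"group {group!r}: zero age variance, curve omitted")
            continue
        curves.append(
            BirthCurve(
                group=str(group),
                location=loc_label,
                mu=float(ages.mean()),
                sigma=sigma,
                proportion=len(ages) / n_total,
            )
        )
    return curves


def fate_birth_curves(
    nrpc_cells: pd.DataFrame,
    location: str | None = None,
    fate_col: str = "fate",
    n_downsample: int = 20000,
    seed: int | None = None,
) -> list[BirthCurve]:
    """Birth curves for neurogenic progenitors grouped by inferred fate.

    Cells with undetermined (empty) fate are excluded from the proportions'
    denominator.
    """
    return estimate_birth_curves(
        nrpc_cells, group_col=fate_col, location=location,
        n_downsample=n_downsample, seed=seed,
    )


def birth_curve_table(curves: list[BirthCurve]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in curves])
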