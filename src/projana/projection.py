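"""Projection curves and their summary statistics.

The projection w(x) of a test genome onto a reference panel of n chromosomes
is, for each derived-allele frequency category x = i/n (i = 1..n-1), the
probability that the test genome carries the derived allele at sites where
the panel frequency is x, normalised by x itself.  The normalisation makes a
test genome drawn from the reference population score w(x) = 1 at every
frequency: a panel chromosome carries a derived allele at frequency x with
probability exactly x.

Summary statistics:

* MPV — the mean of w over defined categories with x > 0.5 (low for test
  genomes from long-diverged populations, 1 for panel members);
* LSS — the sum over categories of squared differences between two curves,
  or between a curve and the horizontal line w(x) = 1.

For the simplest case — a test lineage separated from the panel's population
by t generations with no size changes or gene flow — the projection is flat
at exp(-t / (2N)); see :func:`closed_form_projection`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "ProjectionCurve",
    "ProjectionSummary",
    "compute_projection",
    "mpv",
    "lss",
    "closed_form_projection",
    "rebin_projection",
    "constant_curve",
    "summarize",
]

#: number of equal-width bins used when two curves live on different grids
DEFAULT_COMPARISON_BINS = 25


@dataclass(frozen=True)
class ProjectionCurve:
    """w indexed by derived-allele frequency category.

    ``x`` holds the category frequencies (i/n on the native grid, weighted
    bin centres after rebinning); ``sites`` and ``derived`` are the per-
    category totals of observed sites and of sites where the test genome was
    called derived.  They are floats so that expectation-mode simulation can
    produce fractional weights; on real data they are whole numbers.
    Categories with zero sites are *undefined*: ``w`` is NaN there and every
    statistic skips them.
    """

    x: np.ndarray
    sites: np.ndarray
    derived: np.ndarray
    panel_size: int | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        s = np.asarray(self.sites, dtype=float)
        d = np.asarray(self.derived, dtype=float)
        if not (x.shape == s.shape == d.shape):
            raise ValueError("x, sites and derived must have equal length")
        if np.any((d - s) > 1e-9):
            raise ValueError("derived count cannot exceed site count")
        if np.any(x <= 0) or np.any(x >= 1):
            raise ValueError("frequency categories must lie strictly in (0, 1)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "sites", s)
        object.__setattr__(self, "derived", d)

    # ------------------------------------------------------------------
    @classmethod
    def from_site_counts(
        cls, derived_count: np.ndarray, test_derived: np.ndarray, panel_size: int
    ) -> "ProjectionCurve":
        """Tally per-site (panel derived count, test allele) pairs.

        Monomorphic panel categories (count 0 or n) are excluded.
        """
        derived_count = np.asarray(derived_count)
        test_derived = np.asarray(test_derived).astype(bool)
        n = int(panel_size)
        poly = (derived_count >= 1) & (derived_count <= n - 1)
        sites = np.bincount(derived_count[poly], minlength=n + 1)[1:n]
        der = np.bincount(derived_count[poly & test_derived], minlength=n + 1)[1:n]
        return cls.from_category_weights(n, sites, der)

    @classmethod
    def from_category_weights(cls, panel_size, sites, derived) -> "ProjectionCurve":
        n = int(panel_size)
        x = np.arange(1, n) / n
        return cls(x, np.asarray(sites, float), np.asarray(derived, float), n)

    # ------------------------------------------------------------------
    @property
    def defined(self) -> np.ndarray:
        return self.sites > 0

    @property
    def raw_fraction(self) -> np.ndarray:
        """Unnormalised derived fraction per category (NaN where undefined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.defined, self.derived / self.sites, np.nan)

    @property
    def w(self) -> np.ndarray:
        """The projection: derived fraction divided by x (NaN where undefined)."""
        return self.raw_fraction / self.x

    @property
    def total_sites(self) -> float:
        return float(self.sites.sum())

    def on_native_grid(self, other: "ProjectionCurve") -> bool:
        return self.x.shape == other.x.shape and np.allclose(self.x, other.x)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "w": self.w, "sites": self.sites, "derived": self.derived}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "ProjectionCurve":
        df = pd.read_csv(path, sep="\t")
        x = df["x"].to_numpy()
        n = None
        # recognise a native i/n grid
        if len(x) > 0:
            cand = int(round(1 / np.min(np.diff(np.concatenate([[0.0], x])))))
            if len(x) == cand - 1 and np.allclose(x, np.arange(1, cand) / cand):
                n = cand
        return cls(x, df["sites"].to_numpy(), df["derived"].to_numpy(), n)


def compute_projection(observations: Iterable) -> ProjectionCurve:
    """Projection curve from per-site observations (see
    :class:`projana.siteio.SiteObservation`).

    Uses only sites that pass all filters and have a non-missing test call;
    all observations must share one panel size.
    """
    usable = [
        o for o in observations if o.pass_filters and o.test_call != "missing"
    ]
    if not usable:
        raise ValueError("no usable observations: all sites filtered or missing")
    sizes = {o.panel.panel_size for o in usable}
    if len(sizes) != 1:
        raise ValueError(f"mixed panel sizes in input: {sorted(sizes)}")
    n = sizes.pop()
    counts = np.array([o.panel.derived_count for o in usable])
    test = np.array([o.test_call == "derived" for o in usable])
    return ProjectionCurve.from_site_counts(counts, test, n)


def mpv(curve: ProjectionCurve, site_weighted: bool = False) -> float:
    """Mean projection over defined categories with x strictly above 0.5."""
    sel = curve.defined & (curve.x > 0.5)
    if not sel.any():
        raise ValueError("no defined frequency categories with x > 0.5")
    if site_weighted:
        return float(np.average(curve.w[sel], weights=curve.sites[sel]))
    return float(curve.w[sel].mean())


def lss(
    a: ProjectionCurve,
    b: Union[ProjectionCurve, float, None] = None,
    num_bins: int = DEFAULT_COMPARISON_BINS,
) -> float:
    """Sum of squared differences between two projection curves.

    ``b`` may be another curve, a constant (default 1.0, the panel-member
    line), or None for the same.  Curves on different grids are first pooled
    onto a common ``num_bins`` equal-width grid.
    """
    if b is None:
        b = 1.0
    if isinstance(b, (int, float)):
        sel = a.defined
        return float(np.sum((a.w[sel] - float(b)) ** 2))
    if not a.on_native_grid(b):
        a = rebin_projection(a, num_bins)
        b = rebin_projection(b, num_bins)
    sel = a.defined & b.defined
    if not sel.any():
        raise ValueError("curves share no defined frequency categories")
    return float(np.sum((a.w[sel] - b.w[sel]) ** 2))


def closed_form_projection(t: float, n_diploid: float) -> float:
    """exp(-t / (2N)): the flat projection of a test lineage separated from
    the panel's population by ``t`` generations under constant diploid size
    ``n_diploid``, with no gene flow."""
    if n_diploid <= 0:
        raise ValueError("effective size must be positive")
    if t < 0:
        raise ValueError("time must be non-negative")
    return float(np.exp(-t / (2.0 * n_diploid)))


def rebin_projection(curve: ProjectionCurve, num_bins: int) -> ProjectionCurve:
    """Pool frequency categories into ``num_bins`` equal-width x bins.

    The pooled projection is (total derived / total sites) divided by the
    site-weighted mean x of the bin; site counts are conserved.
    """
    if num_bins < 1:
        raise ValueError("num_bins must be at least 1")
    if num_bins > len(curve.x):
        raise ValueError(
            f"cannot rebin {len(curve.x)} categories into {num_bins} bins"
        )
    idx = np.minimum((curve.x * num_bins).astype(int), num_bins - 1)
    sites = np.bincount(idx, weights=curve.sites, minlength=num_bins)
    der = np.bincount(idx, weights=curve.derived, minlength=num_bins)
    xw = np.bincount(idx, weights=curve.sites * curve.x, minlength=num_bins)
    keep = sites > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = np.where(keep, xw / sites, np.nan)
    # empty bins get a placeholder x at the bin centre (they stay undefined)
    centres = (np.arange(num_bins) + 0.5) / num_bins
    xbar = np.where(keep, xbar, centres)
    return ProjectionCurve(xbar, sites, der, panel_size=None)


def constant_curve(
    value: float, panel_size: int, sites_per_category: float = 1.0
) -> ProjectionCurve:
    """A curve flat at ``value`` on the native i/n grid — e.g. the analytic
    exp(-t/2N) target used when fitting sampling times."""
    n = int(panel_size)
    x = np.arange(1, n) / n
    sites = np.full(n - 1, float(sites_per_category))
    derived = value * x * sites
    return ProjectionCurve(x, sites, derived, n)


@dataclass(frozen=True)
class ProjectionSummary:
    mpv: float
    lss_to_one: float
    total_sites: float

    def to_json(self, path=None, **extra) -> str:
        payload = {
            "mpv": self.mpv,
            "lss_to_one": self.lss_to_one,
            "total_sites": self.total_sites,
        }
        payload.update(extra)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize(curve: ProjectionCurve) -> ProjectionSummary:
    return ProjectionSummary(
        mpv=mpv(curve), lss_to_one=lss(curve, 1.0), total_sites=curve.total_sites
    )
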