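"""Ensemble statistics of anion-contact geometry over docked-pose conformers.

For each motif donor the H...O distances and X-H...O angles are collected
over all conformers in which that donor is engaged, reported as
min-max (mean) ranges, and fitted with a Gaussian to the histogram density.
The fitted mu and sigma, the adjusted R^2 of the fit, and the coefficient of
variation sigma/mu summarise how tight and well-defined the binding geometry
is: a unimodal, narrow distribution (sigma/mu of order 1e-2, adjusted
R^2 >= 0.9) indicates a single well-formed recognition geometry, while a
poor fit flags heterogeneous or multimodal pose sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .core import AnionModel, Structure
from .interactions import (
    DEFAULT_CRITERIA,
    HBondCriteria,
    map_anion_contacts,
)

__all__ = [
    "DonorMetricStats",
    "EnsembleSummary",
    "summarize_ensemble",
    "render_table2",
    "DONOR_LABELS",
]

#: Field-standard donor labels in motif order.
DONOR_LABELS = ("Ca-1", "N0", "N+1")

METRICS = ("distance", "angle")


@dataclass
class DonorMetricStats:
    """Statistics of one donor x metric cell over an ensemble."""

    n: int
    min: Optional[float] = None
    max: Optional[float] = None
    mean: Optional[float] = None
    fit_mu: Optional[float] = None
    fit_sigma: Optional[float] = None
    adj_r2: Optional[float] = None
    r2: Optional[float] = None
    sigma_over_mu: Optional[float] = None

    @property
    def sufficient(self) -> bool:
        return self.min is not None

    @property
    def fit_ok(self) -> bool:
        return self.fit_mu is not None


@dataclass
class EnsembleSummary:
    """Per-donor, per-metric ensemble statistics plus raw values."""

    stats: Dict[Tuple[str, str], DonorMetricStats]
    values: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_models: int = 0

    def cell(self, donor: str, metric: str) -> DonorMetricStats:
        return self.stats[(donor, metric)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (donor, metric), st in self.stats.items():
            rows.append(
                {
                    "donor": donor,
                    "metric": metric,
                    "n": st.n,
                    "min": st.min,
                    "max": st.max,
                    "mean": st.mean,
                    "fit_mu": st.fit_mu,
                    "fit_sigma": st.fit_sigma,
                    "adj_r2": st.adj_r2,
                    "sigma_over_mu": st.sigma_over_mu,
                }
            )
        return pd.DataFrame(rows)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_gaussian(values: np.ndarray) -> Tuple[Optional[float], ...]:
    """(mu, sigma, adj_r2, r2) from a least-squares Gaussian fit to the
    density histogram; Sturges binning.  Degenerate data yields Nones."""
    n = len(values)
    if n < 3 or np.ptp(values) < 1e-9:
        return None, None, None, None
    n_bins = int(math.ceil(math.log2(n))) + 1
    density, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(density.max()), float(values.mean()), max(float(values.std()), 1e-6))
    try:
        with warnings.catch_warnings():
            # the covariance estimate is unused; it is routinely singular
            # for very small samples
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_gaussian, centers, density, p0=p0, maxfev=10000)
    except RuntimeError:
        return None, None, None, None
    amp, mu, sigma = popt
    sigma = abs(float(sigma))
    pred = _gaussian(centers, *popt)
    ss_res = float(np.sum((density - pred) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    if ss_tot <= 0:
        return None, None, None, None
    r2 = 1.0 - ss_res / ss_tot
    if n_bins <= 3:
        adj = r2
    else:
        adj = 1.0 - (1.0 - r2) * (n_bins - 1) / (n_bins - 3)
    return float(mu), sigma, float(adj), float(r2)


def summarize_ensemble(
    models: Sequence[Tuple[Structure, AnionModel]],
    motif_residues: Sequence[int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    min_values: int = 3,
) -> EnsembleSummary:
    """Contact-geometry statistics over a pose ensemble.

    Each model contributes, per donor, the geometry of its best (shortest)
    contact if that donor is engaged; models where a donor is not engaged
    are excluded for that donor only.  Cells with fewer than ``min_values``
    observations are reported as insufficient data rather than raising.
    """
    if len(models) < min_values:
        stats = {
            (d, m): DonorMetricStats(n=0) for d in DONOR_LABELS for m in METRICS
        }
        return EnsembleSummary(stats=stats, n_models=len(models))

    donor_kinds = ("Calpha", "N", "N")
    collected: Dict[Tuple[str, str], List[float]] = {
        (d, m): [] for d in DONOR_LABELS for m in METRICS
    }
    for structure, anion in models:
        inter = map_anion_contacts(structure, anion, motif_residues, criteria)
        for label, kind, res in zip(DONOR_LABELS, donor_kinds, motif_residues):
            contact = inter.donor_contact(kind, res)
            if contact is None:
                continue
            collected[(label, "distance")].append(contact.d_ho)
            collected[(label, "angle")].append(contact.angle_xho)

    stats: Dict[Tuple[str, str], DonorMetricStats] = {}
    values: Dict[Tuple[str, str], np.ndarray] = {}
    for key, vals in collected.items():
        arr = np.asarray(vals, float)
        values[key] = arr
        if len(arr) < min_values:
            stats[key] = DonorMetricStats(n=len(arr))
            continue
        mu, sigma, adj, r2 = _fit_gaussian(arr)
        st = DonorMetricStats(
            n=len(arr),
            min=float(arr.min()),
            max=float(arr.max()),
            mean=float(arr.mean()),
            fit_mu=mu,
            fit_sigma=sigma,
            adj_r2=adj,
            r2=r2,
            sigma_over_mu=(sigma / abs(mu)) if (mu not in (None, 0.0) and sigma is not None) else None,
        )
        stats[key] = st
    return EnsembleSummary(stats=stats, values=values, n_models=len(models))


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def _fmt_cell(st: DonorMetricStats, decimals: int = 2) -> str:
    if not st.sufficient:
        return "—"
    return (
        f"{st.min:.{decimals}f}–{st.max:.{decimals}f} ({st.mean:.{decimals}f})"
    )


def render_table2(
    summaries: Mapping[Tuple[str, str, str], EnsembleSummary],
    fmt: str = "markdown",
) -> str:
    """Range "(mean)" report over (peptide, conformation, anion) summaries.

    Rows are (peptide, conformation) groups in input order; for each anion
    present the three donor distance columns and three angle columns are
    rendered as ``min–max (mean)`` cells, missing anions as em-dashes.
    """
    if not summaries:
        raise ValueError("no summaries to render")
    if fmt not in ("markdown", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")

    anions = []
    for (_pep, _conf, anion) in summaries:
        if anion not in anions:
            anions.append(anion)
    groups: List[Tuple[str, str]] = []
    for (pep, conf, _anion) in summaries:
        if (pep, conf) not in groups:
            groups.append((pep, conf))

    header = ["Peptide", "Conformation"]
    for anion in anions:
        for metric, unit in (("distance", "Å"), ("angle", "°")):
            for donor in DONOR_LABELS:
                header.append(f"{anion} {donor} {metric} ({unit})")

    rows: List[List[str]] = []
    for pep, conf in groups:
        row = [pep, conf]
        for anion in anions:
            summary = summaries.get((pep, conf, anion))
            for metric in METRICS:
                for donor in DONOR_LABELS:
                    if summary is None:
                        row.append("—")
                    else:
                        row.append(_fmt_cell(summary.cell(donor, metric)))
        rows.append(row)

    if fmt == "tsv":
        lines = ["\t".join(header)]
        lines += ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"

    widths = [max(len(header[k]), *(len(r[k]) for r in rows)) for k in range(len(header))]
    def mdrow(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [mdrow(header), mdrow(["-" * w for w in widths])]
    lines += [mdrow(r) for r in rows]
    return "\n".join(lines) + "\n"
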