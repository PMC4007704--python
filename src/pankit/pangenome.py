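"""Pan-/core-genome accumulation curves, Heaps'-law fitting and the
open/closed classification.

For each ordering of the genome panel, pan(N) counts the gene families seen
in the first N genomes and core(N) those present in every one of them. The
number of previously unseen families contributed by the Nth genome,
new(N) = pan(N) - pan(N-1), decays as a power law kappa * N^(-alpha) under
Heaps' law; alpha > 1 marks a closed pan-genome (the discovery series
converges), alpha < 1 an open one.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError, IntegrityError, ValidationError
from .families import GeneFamily

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Families x genomes copy-count matrix."""

    families: list[str]
    genomes: list[str]
    counts: np.ndarray  # shape (F, G), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.families), len(self.genomes)):
            raise ValidationError(
                f"presence matrix shape {self.counts.shape} does not match "
                f"{len(self.families)} families x {len(self.genomes)} genomes"
            )
        if (self.counts < 0).any():
            raise ValidationError("presence matrix has negative counts")
        if self.counts.shape[0] and (self.counts.sum(axis=1) == 0).any():
            raise ValidationError("presence matrix contains an all-zero family row")

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence (copy count >= 1); paralogues do not inflate counts."""
        return self.counts >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.families, columns=self.genomes)


def presence_matrix(families: Sequence[GeneFamily], genomes: Sequence[str]) -> PresenceMatrix:
    """Build the families x genomes copy-count matrix from classified families."""
    genomes = list(genomes)
    gidx = {g: j for j, g in enumerate(genomes)}
    counts = np.zeros((len(families), len(genomes)), dtype=int)
    for i, fam in enumerate(families):
        for genome, k in fam.copy_profile.items():
            if genome not in gidx:
                raise IntegrityError(f"family {fam.family_id} references unknown genome {genome!r}")
            counts[i, gidx[genome]] = k
    return PresenceMatrix([f.family_id for f in families], genomes, counts)


def lower_median(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Median taking the lower of the two middle values for even counts."""
    arr = np.sort(np.asarray(values), axis=axis)
    idx = (arr.shape[axis] - 1) // 2
    return np.take(arr, idx, axis=axis)


@dataclass
class PangenomeCurve:
    """Per-permutation pan/core/new counts vs number of genomes, plus medians.

    Arrays have shape (n_permutations, G); column N-1 holds the value after
    adding the Nth genome. new(1) is stored as pan(1) for alignment; fits and
    rate reports only use new(N) for N >= 2.
    """

    pan: np.ndarray
    core: np.ndarray
    new: np.ndarray
    exhaustive: bool = False
    seed: Optional[int] = None
    median_pan: np.ndarray = field(init=False)
    median_core: np.ndarray = field(init=False)
    median_new: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pan = np.atleast_2d(np.asarray(self.pan))
        self.core = np.atleast_2d(np.asarray(self.core))
        self.new = np.atleast_2d(np.asarray(self.new))
        self.median_pan = lower_median(self.pan, axis=0)
        self.median_core = lower_median(self.core, axis=0)
        self.median_new = lower_median(self.new, axis=0)

    @property
    def n_genomes(self) -> int:
        return self.pan.shape[1]

    @property
    def n_permutations(self) -> int:
        return self.pan.shape[0]


def accumulation_curves(
    m: PresenceMatrix,
    n_permutations: int = 1000,
    exhaustive_max: int = 8,
    seed: Optional[int] = None,
) -> PangenomeCurve:
    """Compute pan/core/new accumulation curves over genome orderings.

    All G! orderings are used when G <= exhaustive_max; otherwise
    ``n_permutations`` uniform random orderings are drawn with the given seed.
    Monotonicity per ordering and permutation-independence of the final pan
    and core counts are asserted on every run.
    """
    g = len(m.genomes)
    if g < 2:
        raise ConfigError("accumulation curves require at least 2 genomes")
    pres = m.presence
    if g <= exhaustive_max:
        orderings = np.array(list(itertools.permutations(range(g))), dtype=int)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        orderings = np.array([rng.permutation(g) for _ in range(n_permutations)], dtype=int)
        exhaustive = False

    n_ord = orderings.shape[0]
    pan = np.empty((n_ord, g), dtype=int)
    core = np.empty((n_ord, g), dtype=int)
    for i, perm in enumerate(orderings):
        sub = pres[:, perm]
        pan[i] = np.logical_or.accumulate(sub, axis=1).sum(axis=0)
        core[i] = np.logical_and.accumulate(sub, axis=1).sum(axis=0)
    new = np.diff(pan, axis=1, prepend=0)

    if (np.diff(pan, axis=1) < 0).any() or (np.diff(core, axis=1) > 0).any():
        raise IntegrityError("accumulation curves violate monotonicity")
    if len(set(pan[:, -1])) != 1 or len(set(core[:, -1])) != 1:
        raise IntegrityError("final pan/core counts depend on the ordering")
    return PangenomeCurve(pan=pan, core=core, new=new, exhaustive=exhaustive, seed=seed)


@dataclass
class HeapsFit:
    """Fitted accumulation models and the open/closed call.

    new(N) ~ kappa_new * N^(-alpha); pan(N) ~ kappa_pan * N^gamma;
    core(N) ~ core_a * exp(-(N-1)/core_tau) + core_omega.
    The pan-genome is called closed iff alpha > 1.
    """

    kappa_new: float
    alpha: float
    kappa_pan: float
    gamma: float
    core_a: float
    core_tau: float
    core_omega: float
    openness_call: str

    def as_dict(self) -> dict:
        return {
            "new_gene_fit": {"kappa": self.kappa_new, "alpha": self.alpha},
            "pan_fit": {"kappa": self.kappa_pan, "gamma": self.gamma},
            "core_fit": {"a": self.core_a, "tau": self.core_tau, "omega": self.core_omega},
            "openness_call": self.openness_call,
        }


def fit_models(curve: PangenomeCurve) -> HeapsFit:
    """Fit the new-gene power law, the pan power law and the core decay.

    The new-gene fit is ordinary least squares of log(median_new(N)) on
    log(N) for N = 2..G, skipping zero medians (log domain); the core fit is
    nonlinear least squares of an exponential decay with offset.
    """
    g = curve.n_genomes
    if g < 4:
        raise ConfigError("model fitting requires at least 4 genomes")

    n_axis = np.arange(1, g + 1, dtype=float)
    new_n = n_axis[1:]
    new_y = np.asarray(curve.median_new[1:], dtype=float)
    mask = new_y > 0
    if mask.sum() < 2:
        raise FitError("all new-gene medians are zero: degenerate panel")
    slope, intercept = np.polyfit(np.log(new_n[mask]), np.log(new_y[mask]), 1)
    alpha = -slope
    kappa_new = math.exp(intercept)

    pan_y = np.asarray(curve.median_pan, dtype=float)
    slope_p, intercept_p = np.polyfit(np.log(n_axis), np.log(pan_y), 1)
    gamma = slope_p
    kappa_pan = math.exp(intercept_p)

    core_y = np.asarray(curve.median_core, dtype=float)
    omega0 = core_y[-1]
    a0 = max(core_y[0] - omega0, 1e-9)
    p0 = (a0, 2.0, omega0)
    try:
        popt, _ = curve_fit(
            lambda n, a, tau, omega: a * np.exp(-(n - 1) / tau) + omega,
            n_axis,
            core_y,
            p0=p0,
            maxfev=20000,
        )
        core_a, core_tau, core_omega = (float(v) for v in popt)
    except RuntimeError:
        logger.warning("core-curve fit did not converge; reporting initial parameters")
        core_a, core_tau, core_omega = p0

    return HeapsFit(
        kappa_new=kappa_new,
        alpha=float(alpha),
        kappa_pan=kappa_pan,
        gamma=float(gamma),
        core_a=core_a,
        core_tau=core_tau,
        core_omega=core_omega,
        openness_call="closed" if alpha > 1 else "open",
    )


def new_gene_rate(curve: PangenomeCurve, k: int = 9) -> float:
    """Average number of new gene families per added genome over the first k
    additions (N = 2..k+1, truncated at G)."""
    g = curve.n_genomes
    upper = min(k + 1, g)
    vals = curve.median_new[1:upper]
    if len(vals) == 0:
        raise ConfigError("need at least 2 genomes for a new-gene rate")
    return float(np.mean(vals))


def curve_report(curve: PangenomeCurve, fit: HeapsFit, k: int = 9) -> dict:
    """JSON-serializable report of the accumulation analysis."""
    g = curve.n_genomes
    return {
        "n_genomes": g,
        "n_permutations": curve.n_permutations,
        "exhaustive": curve.exhaustive,
        "pan_final": int(curve.median_pan[-1]),
        "core_final": int(curve.median_core[-1]),
        "median_pan": [int(v) for v in curve.median_pan],
        "median_core": [int(v) for v in curve.median_core],
        "median_new": [int(v) for v in curve.median_new],
        "new_gene_fit": f"new(N) = {fit.kappa_new:.4g} * N^(-{fit.alpha:.4g})",
        "pan_fit": f"pan(N) = {fit.kappa_pan:.4g} * N^({fit.gamma:.4g})",
        "core_fit": (
            f"core(N) = {fit.core_a:.4g} * exp(-(N-1)/{fit.core_tau:.4g}) "
            f"+ {fit.core_omega:.4g}"
        ),
        "openness_call": fit.openness_call,
        "alpha": fit.alpha,
        "avg_new_gene_rate": new_gene_rate(curve, k=k),
        "avg_new_gene_rate_k": k,
    }


def curves_frame(curve: PangenomeCurve) -> pd.DataFrame:
    """Per-N medians and quartiles as a tidy table."""
    g = curve.n_genomes
    q1_pan = np.percentile(curve.pan, 25, axis=0)
    q3_pan = np.percentile(curve.pan, 75, axis=0)
    q1_core = np.percentile(curve.core, 25, axis=0)
    q3_core = np.percentile(curve.core, 75, axis=0)
    return pd.DataFrame(
        {
            "n_genomes": np.arange(1, g + 1),
            "median_pan": curve.median_pan,
            "median_core": curve.median_core,
            "median_new": curve.median_new,
            "q1_pan": q1_pan,
            "q3_pan": q3_pan,
            "q1_core": q1_core,
            "q3_core": q3_core,
        }
    )
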