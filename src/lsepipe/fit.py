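"""Maximum-likelihood fitting of the site-class models and downstream calls.

Covers model fitting (bounded L-BFGS-B with deterministic multi-starts for
the positive-selection class), likelihood-ratio tests with Bonferroni
correction, empirical-Bayes per-site P(omega > 1), and synonymous /
nonsynonymous site-opportunity counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from . import geneticcode as gc
from . import likelihood as lk
from . import sitemodels as sm
from .qc import CodonAlignment

POSTERIOR_FLAG_CUTOFF = 0.95

_BOUNDS = {
    "kappa": (0.05, 50.0),
    "scale": (1e-4, 100.0),
    "prop": (1e-4, 1.0 - 1e-4),
    "omega0": (1e-4, 0.999),
    "omega_pos": (1.0 + 1e-6, 50.0),
    "beta_shape": (0.05, 25.0),
}

#: deterministic starting values for the omega>1 class (M2a / M8)
OMEGA_POS_STARTS = (3.0, 1.5, 8.0)


@dataclass
class SiteModelFit:
    model: str
    lnL: float
    kappa: float
    scale: float
    spec: sm.SiteModelSpec
    pi: np.ndarray
    site_posterior_pos: np.ndarray  # per codon site, P(omega > 1)
    class_site_posteriors: np.ndarray  # (n_classes, n_sites)
    converged: bool = True
    n_evaluations: int = 0

    @property
    def params(self) -> dict:
        return dict(self.spec.params, kappa=self.kappa, scale=self.scale)

    @property
    def flagged_sites(self) -> list[int]:
        """1-based codon positions with P(omega>1) strictly above 0.95."""
        return [
            int(i) + 1
            for i in np.flatnonzero(self.site_posterior_pos > POSTERIOR_FLAG_CUTOFF)
        ]


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float
    p_adjusted: float = np.nan
    significant: bool = False


class FitError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _spec_from_theta(model: str, theta: np.ndarray) -> sm.SiteModelSpec:
    if model == "M1a":
        _, _, p0, omega0 = theta
        return sm.m1a(p0, omega0)
    if model == "M2a":
        _, _, p0, pr1, omega0, omega2 = theta
        p1 = (1.0 - p0) * pr1
        return sm.m2a(p0, p1, omega0, omega2)
    if model == "M8":
        _, _, p0, p, q, omega_s = theta
        return sm.m8(p0, p, q, omega_s)
    if model == "M8a":
        _, _, p0, p, q = theta
        return sm.m8a(p0, p, q)
    raise ValueError(f"unknown model {model!r}")


def _starts_and_bounds(model: str, init: "SiteModelFit | None", n_starts: int):
    b = _BOUNDS
    if init is not None:
        kappa0, scale0 = init.kappa, init.scale
        p00 = init.spec.params.get("p0", 0.7)
        om0 = init.spec.params.get("omega0", 0.2)
    else:
        kappa0, scale0, p00, om0 = 2.0, 1.0, 0.7, 0.2
    if model == "M1a":
        starts = [np.array([kappa0, scale0, p00, om0])]
        bounds = [b["kappa"], b["scale"], b["prop"], b["omega0"]]
    elif model == "M2a":
        starts = [
            np.array([kappa0, scale0, max(p00 - 0.05, 0.05), 0.8, om0, w2])
            for w2 in OMEGA_POS_STARTS[:n_starts]
        ]
        # null-equivalent start (p2 -> 0, omega2 -> 1) guarantees the fitted
        # lnL can never fall below the nested M1a optimum
        starts.append(
            np.array([kappa0, scale0, p00, 1.0 - 1e-4, om0, 1.0 + 1e-6])
        )
        bounds = [b["kappa"], b["scale"], b["prop"], b["prop"],
                  b["omega0"], b["omega_pos"]]
    elif model == "M8a":
        p0b = init.spec.params.get("p", 0.5) if init is not None else 0.5
        q0b = init.spec.params.get("q", 1.5) if init is not None else 1.5
        starts = [np.array([kappa0, scale0, 0.9, p0b, q0b])]
        bounds = [b["kappa"], b["scale"], b["prop"],
                  b["beta_shape"], b["beta_shape"]]
    elif model == "M8":
        p0b = init.spec.params.get("p", 0.5) if init is not None else 0.5
        q0b = init.spec.params.get("q", 1.5) if init is not None else 1.5
        starts = [
            np.array([kappa0, scale0, 0.9, p0b, q0b, w2])
            for w2 in OMEGA_POS_STARTS[:n_starts]
        ]
        if init is not None and init.model == "M8a":
            p0_null = init.spec.params.get("p0", 0.9)
            starts.append(
                np.array([kappa0, scale0, p0_null, p0b, q0b, 1.0 + 1e-6])
            )
        bounds = [b["kappa"], b["scale"], b["prop"],
                  b["beta_shape"], b["beta_shape"], b["omega_pos"]]
    else:
        raise ValueError(f"unknown model {model!r}")
    return starts, bounds


def fit_site_model(
    alignment: CodonAlignment,
    tree,
    model: str,
    pi: np.ndarray | None = None,
    init: SiteModelFit | None = None,
    n_starts: int = len(OMEGA_POS_STARTS),
    maxfun: int = 600,
    tol: float = 1e-8,
) -> SiteModelFit:
    """Fit one site model by bounded multi-start maximum likelihood.

    Branch lengths come from the input tree, rescaled by one free
    multiplier. Codon frequencies default to F3x4 from the alignment.
    Deterministic: starts are fixed, no randomness involved.
    """
    if model not in sm.MODELS:
        raise ValueError(f"unknown model {model!r}")
    data = alignment if isinstance(alignment, lk.PhyloData) else lk.PhyloData(alignment, tree)
    if pi is None:
        pi = data.f3x4()

    n_eval = 0

    def objective(theta):
        nonlocal n_eval
        n_eval += 1
        try:
            spec = _spec_from_theta(model, theta)
            return -lk.log_likelihood(data, theta[0], theta[1], spec, pi)
        except (ValueError, FloatingPointError):
            return 1e12

    starts, bounds = _starts_and_bounds(model, init, n_starts)
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": maxfun, "ftol": tol, "gtol": 1e-7},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    spec = _spec_from_theta(model, theta)
    cls = lk.class_pattern_loglikes(data, theta[0], theta[1], spec.omegas, spec.weights, pi)
    lnl = float(np.dot(data.pattern_weights, lk.mixture_pattern_loglikes(cls, spec.weights)))
    post = lk.class_posteriors(cls, spec.weights)
    class_site = data.expand(post)
    pos = class_site[spec.positive_mask].sum(axis=0) if spec.positive_mask.any() \
        else np.zeros(data.n_sites)
    fit = SiteModelFit(
        model=model, lnL=lnl, kappa=float(theta[0]), scale=float(theta[1]),
        spec=spec, pi=pi, site_posterior_pos=pos,
        class_site_posteriors=class_site,
        converged=any_success, n_evaluations=n_eval,
    )
    if not np.isfinite(lnl):
        raise FitError(f"{model} optimisation failed to reach a finite lnL", best=fit)
    return fit


def lrt_positive_selection(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LRTResult:
    """LRT of a positive-selection model against its nested nearly-neutral null.

    2*(lnL_alt - lnL_null) is clamped at zero and compared to chi-square
    with df = 2 (M1a vs M2a) or df = 1 (M8a vs M8).
    """
    pair = (null_fit.model, alt_fit.model)
    if pair not in sm.NESTED_PAIRS:
        raise ValueError(f"{pair} is not a supported nested model pair")
    df = sm.NESTED_PAIRS[pair]
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(
        null_model=pair[0], alt_model=pair[1],
        statistic=stat, df=df, p_value=p,
    )


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """min(1, m * p) for each p; m is the test family size."""
    p_values = np.asarray(p_values, dtype=float)
    if m < p_values.size:
        raise ValueError("family size m smaller than number of p-values")
    return np.minimum(1.0, m * p_values)


def site_posterior_omega_gt1(alt_fit: SiteModelFit):
    """Per-site P(omega > 1) and 1-based flagged positions (strictly > 0.95)."""
    if not alt_fit.spec.positive_mask.any():
        raise ValueError(
            f"{alt_fit.model} has no omega>1 class; posterior calling needs "
            "an alternative-model fit (M2a or M8)"
        )
    return alt_fit.site_posterior_pos, alt_fit.flagged_sites


@dataclass
class SiteCounts:
    ns_sites: float
    s_sites: float

    @property
    def total(self) -> float:
        return self.ns_sites + self.s_sites


def _codon_syn_fraction(kappa: float) -> np.ndarray:
    """Per sense codon, the synonymous fraction of its mutational opportunity.

    Each codon's 9 single-nucleotide mutations are weighted kappa
    (transitions) or 1 (transversions); mutations to stop codons carry zero
    weight but positions still count for 3 sites total.
    """
    weights = np.where(gc.MUTATION_TS, kappa, 1.0)
    weights[gc.MUTATION_TARGETS < 0] = 0.0
    syn = (weights * gc.MUTATION_SYN).sum(axis=1)
    tot = weights.sum(axis=1)
    return syn / tot


def count_syn_nonsyn_sites(alignment: CodonAlignment, kappa: float) -> SiteCounts:
    """Synonymous/nonsynonymous site opportunities, averaged over sequences.

    Per codon column the synonymous fraction is averaged over the sequences
    with data at that column, so NSsites + Ssites = 3 * codon count.
    """
    frac = _codon_syn_fraction(kappa)
    mat = alignment.codon_matrix()
    present = mat >= 0
    per_seq = np.where(present, frac[np.clip(mat, 0, None)], 0.0)
    denom = np.maximum(present.sum(axis=0), 1)
    col_syn_frac = per_seq.sum(axis=0) / denom
    # fully-missing columns get the neutral prior of their opportunity split
    empty = present.sum(axis=0) == 0
    if empty.any():
        col_syn_frac[empty] = frac.mean()
    s_sites = float(3.0 * col_syn_frac.sum())
    total = 3.0 * alignment.n_codons
    return SiteCounts(ns_sites=total - s_sites, s_sites=s_sites)


def fit_model_pairs(
    alignment: CodonAlignment,
    tree,
    models=("M1a", "M2a", "M8a", "M8"),
    pi: np.ndarray | None = None,
    n_starts: int = len(OMEGA_POS_STARTS),
) -> dict[str, SiteModelFit]:
    """Fit the requested models, seeding alternatives from their nulls."""
    data = lk.PhyloData(alignment, tree)
    if pi is None:
        pi = data.f3x4()
    fits: dict[str, SiteModelFit] = {}
    for model in models:
        init = None
        if model == "M2a":
            init = fits.get("M1a")
        elif model == "M8":
            init = fits.get("M8a")
        elif model == "M8a":
            init = fits.get("M1a")
        fits[model] = fit_site_model(
            data, tree, model, pi=pi, init=init, n_starts=n_starts
        )
    return fits
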