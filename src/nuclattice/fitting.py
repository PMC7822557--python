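"""Parameter fitting of the lattice model against reference occupancy.

The free parameters are the per-species concentration c and specificity
gamma (optionally plus the remodeling barrier height h and width w).  The
objective is the per-bp root-mean-square deviation between the model's total
nucleosome occupancy and the reference track, evaluated over the training
chromosomes.  Minimisation uses the Nelder-Mead simplex embedded in a
simulated-annealing loop: at each temperature the simplex is run for a
bounded number of iterations from a perturbed restart, moves are accepted by
the Metropolis rule, and the temperature cools geometrically.  Bounds are
enforced by smooth transformations (log for c, logistic for the bounded
parameters), so the simplex itself is unconstrained.

Overfitting is controlled by chromosome-level 70/30 cross-validation,
repeated over several random shuffles; the shuffle whose fitted parameters
give the best fraction of recovered NDRs (P_NDR) on held-out chromosomes is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .lattice import LatticeSystem, solve
from .ndr import NDR, ReferenceTrack, annotate_ndrs, evaluate_prediction, rmsd
from .remodeling import RemodelingParams, remodel_occupancy

# default bounds per parameter kind
BOUNDS = {"c": (0.0, 1e3), "gamma": (0.0, 5.0), "h": (-50.0, 50.0), "w": (1.0, 500.0)}


class _Transform:
    """Map bounded parameters to an unconstrained internal scale."""

    def __init__(self, names: list[str]):
        self.names = names
        self.kinds = [n.rsplit(".", 1)[-1] for n in names]

    def to_internal(self, values: np.ndarray) -> np.ndarray:
        out = np.empty(len(values))
        for i, (v, k) in enumerate(zip(values, self.kinds)):
            lo, hi = BOUNDS[k]
            if k == "c":
                out[i] = np.log(max(v, 1e-12))
            else:
                frac = np.clip((v - lo) / (hi - lo), 1e-9, 1 - 1e-9)
                out[i] = logit(frac)
        return out

    def from_internal(self, theta: np.ndarray) -> np.ndarray:
        out = np.empty(len(theta))
        for i, (t, k) in enumerate(zip(theta, self.kinds)):
            lo, hi = BOUNDS[k]
            out[i] = np.exp(t) if k == "c" else lo + (hi - lo) * expit(t)
        return out


@dataclass
class FitConfig:
    """Free-parameter selection, CV protocol, and annealing schedule.

    `free` lists parameters as "<factor>.c" / "<factor>.gamma" (plus
    "remodel.h" / "remodel.w" when a remodeling template is supplied).
    """

    free: tuple[str, ...]
    train_fraction: float = 0.70
    shuffles: int = 5
    t0: float = 1.0
    cooling: float = 0.9
    n_temps: int = 50
    nm_maxiter: int = 100
    perturb_scale: float = 0.5
    xatol: float = 1e-4
    fatol: float = 1e-7
    seed: int | None = None
    remodel: RemodelingParams | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.shuffles < 1:
            raise ValueError("shuffles must be >= 1")


@dataclass
class FitResult:
    params: dict[str, float]
    train_rmsd: float
    test_rmsd: float
    p_ndr: float
    auc: float
    trace: list[float]
    train_chroms: list[str]
    test_chroms: list[str]
    converged: bool = True


def _apply_params(
    systems: dict[str, LatticeSystem], params: dict[str, float]
) -> dict[str, LatticeSystem]:
    out = {}
    for chrom, sys in systems.items():
        s = sys.copy()
        for key, val in params.items():
            name, kind = key.rsplit(".", 1)
            if name == "remodel":
                continue
            try:
                f = s.factor(name)
            except KeyError:
                continue
            setattr(f, "c" if kind == "c" else "gamma", float(val))
        out[chrom] = s
    return out


def predict_occupancy(
    systems: dict[str, LatticeSystem],
    params: dict[str, float],
    remodel: RemodelingParams | None = None,
    nucleosome: str = "nucleosome",
) -> dict[str, np.ndarray]:
    """Nucleosome occupancy per chromosome under a parameter assignment."""
    applied = _apply_params(systems, params)
    out = {}
    for chrom, s in applied.items():
        if remodel is not None:
            rp = replace(
                remodel,
                h=params.get("remodel.h", remodel.h),
                w=params.get("remodel.w", remodel.w),
            )
            out[chrom] = remodel_occupancy(s, rp, nucleosome).occupancy
        else:
            out[chrom] = solve(s)[nucleosome].occupancy
    return out


def objective(
    params: dict[str, float],
    systems: dict[str, LatticeSystem],
    refs: dict[str, np.ndarray | ReferenceTrack],
    chroms: list[str] | None = None,
    remodel: RemodelingParams | None = None,
    nucleosome: str = "nucleosome",
) -> float:
    """Training RMSD of the model under `params` (length-weighted over
    chromosomes); +inf on numerical failure (rejected move)."""
    if chroms is None:
        chroms = list(systems)
    try:
        occ = predict_occupancy(
            {c: systems[c] for c in chroms}, params, remodel, nucleosome
        )
    except (FloatingPointError, ValueError):
        return np.inf
    sq, n = 0.0, 0
    for c in chroms:
        ref = refs[c]
        y = ref.y if isinstance(ref, ReferenceTrack) else np.asarray(ref, float)
        o = occ[c]
        if not np.all(np.isfinite(o)):
            return np.inf
        sq += float(np.sum((o - y) ** 2))
        n += y.size
    return float(np.sqrt(sq / n))


def _anneal_nm(fun, x0: np.ndarray, cfg: FitConfig, rng: np.random.Generator):
    """Simulated-annealing-wrapped Nelder-Mead.  Returns (best_x, best_f,
    trace, converged)."""
    f0 = fun(x0)
    trace = [f0]
    best_x, best_f = x0.copy(), f0
    if cfg.n_temps == 0 and cfg.nm_maxiter == 0:
        return best_x, best_f, trace, False
    cur_x, cur_f = x0.copy(), f0
    T = cfg.t0
    converged = False
    for _ in range(cfg.n_temps):
        start = cur_x + rng.normal(scale=cfg.perturb_scale * T, size=cur_x.size)
        if cfg.nm_maxiter > 0:
            res = minimize(
                fun,
                start,
                method="Nelder-Mead",
                options={
                    "maxiter": cfg.nm_maxiter,
                    "xatol": cfg.xatol,
                    "fatol": cfg.fatol,
                },
            )
            cand_x, cand_f = res.x, float(res.fun)
        else:
            cand_x, cand_f = start, fun(start)
        # Metropolis on the objective
        if cand_f < cur_f or rng.random() < np.exp(-(cand_f - cur_f) / max(T, 1e-12)):
            cur_x, cur_f = cand_x, cand_f
        if cand_f < best_f:
            best_x, best_f = cand_x.copy(), cand_f
        trace.append(best_f)
        T *= cfg.cooling
    if cfg.nm_maxiter > 0:
        res = minimize(
            fun,
            best_x,
            method="Nelder-Mead",
            options={"maxiter": 50 * max(x0.size, 1) * 4, "xatol": cfg.xatol, "fatol": cfg.fatol},
        )
        if float(res.fun) <= best_f:
            best_x, best_f = res.x, float(res.fun)
            converged = bool(res.success)
        trace.append(best_f)
    return best_x, best_f, trace, converged


def _split(chroms: list[str], frac: float, rng: np.random.Generator):
    chroms = list(chroms)
    rng.shuffle(chroms)
    n_train = int(round(frac * len(chroms)))
    n_train = min(max(n_train, 1), len(chroms) - 1)
    return chroms[:n_train], chroms[n_train:]


def _held_out_metrics(params, systems, refs, ref_ndrs, test, cfg, nucleosome):
    occ = predict_occupancy(
        {c: systems[c] for c in test}, params, cfg.remodel, nucleosome
    )
    test_rmsd = objective(params, systems, refs, test, cfg.remodel, nucleosome)
    # pool held-out chromosomes into one scoring problem
    pred = np.concatenate([occ[c] for c in test])
    offset, ndrs = 0, []
    for c in test:
        for n in ref_ndrs.get(c, []):
            ndrs.append(NDR(n.start + offset, n.end + offset, n.center + offset, n.length))
        offset += occ[c].size
    if ndrs:
        rep = evaluate_prediction(pred, ndrs)
        return test_rmsd, rep.p_ndr, rep.auc
    return test_rmsd, np.nan, np.nan


def fit_parameters(
    systems: dict[str, LatticeSystem],
    refs: dict[str, np.ndarray | ReferenceTrack],
    cfg: FitConfig,
    init: dict[str, float],
    ref_ndrs: dict[str, list[NDR]] | None = None,
    nucleosome: str = "nucleosome",
) -> FitResult:
    """Cross-validated annealed fit.

    For each shuffle: random chromosome-level train/test split, annealed
    Nelder-Mead on the training RMSD, and held-out scoring.  The shuffle with
    the best held-out P_NDR wins (held-out RMSD breaks ties and stands in
    when no held-out NDRs exist).  `init` must assign every free parameter.
    """
    if len(systems) < 2:
        raise ValueError("need >= 2 chromosomes for a train/test split")
    missing = [k for k in cfg.free if k not in init]
    if missing:
        raise ValueError(f"init missing free parameters: {missing}")
    if ref_ndrs is None:
        ref_ndrs = {}
        for c, ref in refs.items():
            y = ref.y if isinstance(ref, ReferenceTrack) else np.asarray(ref, float)
            ref_ndrs[c] = annotate_ndrs(y)
    rng = np.random.default_rng(cfg.seed)
    tf = _Transform(list(cfg.free))
    fixed = {k: v for k, v in init.items() if k not in cfg.free}

    best: FitResult | None = None
    for _ in range(cfg.shuffles):
        train, test = _split(list(systems), cfg.train_fraction, rng)

        def fun(theta: np.ndarray) -> float:
            vals = tf.from_internal(theta)
            params = dict(fixed)
            params.update(zip(cfg.free, vals))
            return objective(params, systems, refs, train, cfg.remodel, nucleosome)

        x0 = tf.to_internal(np.array([init[k] for k in cfg.free]))
        x, f, trace, converged = _anneal_nm(fun, x0, cfg, rng)
        params = dict(fixed)
        params.update(zip(cfg.free, tf.from_internal(x)))
        test_rmsd, p_ndr, auc = _held_out_metrics(
            params, systems, refs, ref_ndrs, test, cfg, nucleosome
        )
        result = FitResult(
            params, f, test_rmsd, p_ndr, auc, trace, train, test, converged
        )
        if best is None or _better(result, best):
            best = result
    return best


def _better(a: FitResult, b: FitResult) -> bool:
    if np.isnan(a.p_ndr) and np.isnan(b.p_ndr):
        return a.test_rmsd < b.test_rmsd
    if np.isnan(b.p_ndr):
        return True
    if np.isnan(a.p_ndr):
        return False
    if a.p_ndr != b.p_ndr:
        return a.p_ndr > b.p_ndr
    return a.test_rmsd < b.test_rmsd


def rank_factors_by_pndr(
    systems: dict[str, LatticeSystem],
    refs: dict[str, np.ndarray | ReferenceTrack],
    candidates: list[str],
    cfg: FitConfig,
    init: dict[str, float],
    nucleosome: str = "nucleosome",
) -> list[tuple[str, float]]:
    """Rank candidate factors by the held-out P_NDR of a nucleosome-plus-one-
    factor model (the protocol behind incremental factor addition).  Factors
    not in `candidates` are silenced with c = 0."""
    ranking = []
    for name in candidates:
        base = dict(init)
        for other in candidates:
            if other != name:
                base[f"{other}.c"] = 0.0
        sub = replace(
            cfg,
            free=tuple(
                k
                for k in cfg.free
                if k.startswith((f"{name}.", f"{nucleosome}."))
            ),
        )
        res = fit_parameters(systems, refs, sub, base, nucleosome=nucleosome)
        ranking.append((name, res.p_ndr))
    ranking.sort(key=lambda t: (-(t[1] if not np.isnan(t[1]) else -1.0)))
    return ranking


def incremental_fit(
    systems: dict[str, LatticeSystem],
    refs: dict[str, np.ndarray | ReferenceTrack],
    candidates: list[str],
    cfg: FitConfig,
    init: dict[str, float],
    nucleosome: str = "nucleosome",
) -> list[tuple[list[str], FitResult]]:
    """Add factors one at a time in ranked order, re-fitting after each
    addition; returns the (factor subset, fit) trajectory."""
    ranking = [n for n, _ in rank_factors_by_pndr(systems, refs, candidates, cfg, init, nucleosome)]
    results = []
    included: list[str] = []
    params = dict(init)
    for name in ranking:
        included.append(name)
        base = dict(params)
        for other in candidates:
            if other not in included:
                base[f"{other}.c"] = 0.0
        sub = replace(
            cfg,
            free=tuple(
                k
                for k in cfg.free
                if k.rsplit(".", 1)[0] in included + [nucleosome]
            ),
        )
        res = fit_parameters(systems, refs, sub, base, nucleosome=nucleosome)
        params.update(res.params)
        results.append((list(included), res))
    return results


__all__ = [
    "BOUNDS",
    "FitConfig",
    "FitResult",
    "objective",
    "predict_occupancy",
    "fit_parameters",
    "rank_factors_by_pndr",
    "incremental_fit",
]
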