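"""Latent-space Bayesian optimization for splicing sequence design.

Searches the VAE latent space for sequences that move a cassette exon's
inclusion toward a target profile under two black-box constraints: the
Levenshtein distance to the start sequence (edit budget tau, evaluated
on decoded sequences) and a PSI floor for the non-target conditions (so
the optimizer cannot simply destroy splicing everywhere).

The surrogate is a Gaussian process (Matern 5/2, ARD) over latents, with
separate GPs for the objective and each constraint. Candidates are
proposed by Thompson sampling inside a trust region around the incumbent
that expands on success and shrinks on failure; feasibility follows the
SCBO rule — prefer feasible candidates, otherwise minimise total
violation. Random-mutation and genetic-algorithm baselines share the
oracle-call accounting and success rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import edlib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .design_vae import SequenceVae
from .tokenizer import BASES

# oracle: sequence -> {condition: psi}
Oracle = Callable[[str], dict]


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    return int(edlib.align(s1, s2, mode="NW", task="distance")["editDistance"])


# ---------------------------------------------------------------------------
# task / result containers
# ---------------------------------------------------------------------------


@dataclass
class DesignTask:
    start_sequence: str
    objective: str  # maximize_psi | minimize_psi | tissue_differential
    target_condition: str
    other_conditions: tuple[str, ...] = ()
    edit_budget: int = 30
    psi_floor: float = 0.05
    success_high: float = 0.5  # PSI the target condition must exceed
    success_low: float = 0.2  # PSI the other conditions must stay below
    oracle_budget: int = 500

    def __post_init__(self):
        if self.edit_budget < 0 or not 0 <= self.psi_floor <= 1 or self.oracle_budget < 1:
            raise ValueError("invalid task: tau >= 0, floor in [0,1], budget >= 1")
        if self.objective not in ("maximize_psi", "minimize_psi", "tissue_differential"):
            raise ValueError(f"unknown objective {self.objective!r}")

    def scalarize(self, vals: dict) -> float:
        y = vals[self.target_condition]
        if self.objective == "minimize_psi":
            return -y
        if self.objective == "tissue_differential":
            others = [vals[c] for c in self.other_conditions]
            return y - (max(others) if others else 0.0)
        return y

    def floor_ok(self, vals: dict) -> bool:
        return all(vals[c] >= self.psi_floor for c in self.other_conditions)

    def is_success(self, vals: dict, lev: int) -> bool:
        if lev > self.edit_budget or not self.floor_ok(vals):
            return False
        if self.objective == "tissue_differential":
            return (vals[self.target_condition] > self.success_high
                    and all(vals[c] < self.success_low for c in self.other_conditions))
        if self.objective == "maximize_psi":
            return vals[self.target_condition] > self.success_high
        return vals[self.target_condition] < self.success_low


@dataclass
class DesignResult:
    sequence: str
    oracle_values: dict
    lev: int
    success: bool
    iteration: int
    method: str

    def __post_init__(self):
        if self.success and self.lev > 10**9:
            raise ValueError("success-flagged candidate violating the edit budget")


@dataclass
class SearchState:
    Z: np.ndarray
    y: np.ndarray
    lev: np.ndarray
    min_other: np.ndarray
    tr_length: float = 0.8
    successes: int = 0
    failures: int = 0
    iteration: int = 0


def _evaluate(task: DesignTask, oracle: Oracle, seq: str, iteration: int,
              method: str) -> DesignResult:
    vals = oracle(seq)
    lev = levenshtein(seq, task.start_sequence)
    return DesignResult(sequence=seq, oracle_values=dict(vals), lev=lev,
                        success=task.is_success(vals, lev),
                        iteration=iteration, method=method)


def _random_mutant(task: DesignTask, rng: np.random.Generator,
                   mer_lengths=(3, 6, 15, 30)) -> str:
    """The start sequence with one random mer substituted."""
    s = task.start_sequence
    ell = min(int(rng.choice(mer_lengths)), task.edit_budget, len(s))
    if ell == 0:
        return s
    off = int(rng.integers(0, len(s) - ell + 1))
    repl = "".join(BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4]
                   for b in s[off:off + ell])
    return s[:off] + repl + s[off + ell:]


# ---------------------------------------------------------------------------
# GP surrogate
# ---------------------------------------------------------------------------


def fit_surrogate(Z: np.ndarray, y: np.ndarray,
                  kernel=None, optimize_hyperparameters: bool = True
                  ) -> GaussianProcessRegressor:
    """Matern 5/2 ARD GP with standardized outputs; refit by marginal
    likelihood. Jitter escalates automatically on degenerate kernels.

    Passing a previously fitted kernel with ``optimize_hyperparameters``
    off reuses its hyperparameters (cheap refit on new data).
    """
    if len(Z) < 2:
        raise ValueError("need at least two observations to fit the surrogate")
    d = Z.shape[1]
    if kernel is None:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(d), length_scale_bounds=(1e-2, 1e3), nu=2.5
        ) + WhiteKernel(1e-6, (1e-8, 1e-1))
    for alpha in (1e-6, 1e-4, 1e-2):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=alpha, normalize_y=True, n_restarts_optimizer=0,
            optimizer="fmin_l_bfgs_b" if optimize_hyperparameters else None)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Z, y)
            return gp
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("kernel matrix degenerate even with jitter 1e-2")


def propose_candidates(
    gp_obj: GaussianProcessRegressor,
    gp_constraints: list[tuple[GaussianProcessRegressor, float]],
    center: np.ndarray,
    tr_length: float,
    scale: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int = 512,
    batch: int = 10,
    anchors: np.ndarray | None = None,
    explore_frac: float = 0.25,
    block_dims: int | None = None,
) -> np.ndarray:
    """Thompson sampling within the trust region, SCBO feasibility rule.

    gp_constraints: (gp, threshold) pairs; a draw is feasible when every
    sampled constraint value is <= its threshold. A fraction of the pool
    explores toward ``anchors`` (e.g. training-corpus latents) so the
    surrogates learn the landscape beyond the trust region; with a
    block-factorized latent (``block_dims`` per block), exploration
    transplants whole anchor block codes. The feasibility rule still
    decides what gets evaluated.
    """
    d = len(center)
    half = 0.5 * tr_length * scale
    cand = center + (rng.random((n_candidates, d)) * 2.0 - 1.0) * half
    # perturb only a subset of dimensions per candidate (TuRBO-style)
    p = min(1.0, 20.0 / d)
    mask = rng.random((n_candidates, d)) < p
    mask[~mask.any(axis=1), rng.integers(0, d, size=int((~mask.any(axis=1)).sum()))] = True
    cand = np.where(mask, cand, center)
    if anchors is not None and len(anchors) and explore_frac > 0:
        n_exp = int(n_candidates * explore_frac)
        idx = rng.integers(0, len(anchors), size=n_exp)
        if block_dims and d % block_dims == 0:
            nb = d // block_dims
            cand[:n_exp] = center
            for j in range(n_exp):
                k = 1 + int(rng.integers(0, 3))  # transplant 1-3 blocks
                for b in rng.choice(nb, size=min(k, nb), replace=False):
                    sl = slice(b * block_dims, (b + 1) * block_dims)
                    cand[j, sl] = anchors[idx[j], sl]
        else:
            alpha = rng.random((n_exp, 1)) ** 2  # bias toward the incumbent
            ray = center + alpha * (anchors[idx] - center)
            jitter = (rng.random((n_exp, d)) * 2.0 - 1.0) * (0.25 * scale)
            cand[:n_exp] = ray + jitter
    seed_obj = int(rng.integers(0, 2**31 - 1))
    y_samp = gp_obj.sample_y(cand, n_samples=batch, random_state=seed_obj)
    c_samps = []
    for gp_c, _ in gp_constraints:
        c_samps.append(gp_c.sample_y(cand, n_samples=batch,
                                     random_state=int(rng.integers(0, 2**31 - 1))))
    chosen = []
    for j in range(batch):
        feas = np.ones(n_candidates, dtype=bool)
        viol = np.zeros(n_candidates)
        for (gp_c, thr), cs in zip(gp_constraints, c_samps):
            v = cs[:, j] - thr
            feas &= v <= 0
            viol += np.maximum(v, 0.0)
        if feas.any():
            pool = np.flatnonzero(feas)
            chosen.append(pool[np.argmax(y_samp[pool, j])])
        else:
            chosen.append(int(np.argmin(viol)))
    return cand[sorted(set(chosen))]


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------


def optimize(
    task: DesignTask,
    oracle: Oracle,
    vae: SequenceVae,
    seed: int = 0,
    n_init: int = 24,
    batch: int = 10,
    n_candidates: int = 512,
    max_gp_points: int = 256,
    tr_init: float = 0.8,
    tr_bounds: tuple[float, float] = (0.03, 2.0),
    tr_success_tol: int = 3,
    tr_fail_tol: int = 5,
    latent_scale: np.ndarray | None = None,
    anchor_latents: np.ndarray | None = None,
    explore_frac: float = 0.25,
) -> list[DesignResult]:
    """Constrained latent-space BO; returns every evaluated candidate.

    Terminates at the task's oracle-call budget. Candidates violating the
    edit budget or the PSI floor are retained in the log (they inform the
    constraint GPs) but can never be success-flagged. Latents that decode
    to an already-scored sequence reuse the cached oracle values without
    spending budget (the oracle is deterministic in a design run).

    ``latent_scale`` sets the per-dimension width of the trust region in
    latent units (e.g. the std of the training corpus embeddings).
    """
    rng = np.random.default_rng(seed)
    L = len(task.start_sequence)
    results: list[DesignResult] = []
    seen: dict[str, DesignResult] = {}
    calls = 0

    def eval_seq(seq: str, it: int) -> tuple[DesignResult | None, bool]:
        """Returns (result, is_new); cached sequences cost no budget."""
        nonlocal calls
        if seq in seen:
            return seen[seq], False
        if calls >= task.oracle_budget:
            return None, False
        res = _evaluate(task, oracle, seq, it, "BO")
        seen[seq] = res
        results.append(res)
        calls += 1
        return res, True

    # initial design: the start sequence and perturbations of it, embedded
    init_seqs = [task.start_sequence]
    while len(init_seqs) < n_init:
        init_seqs.append(_random_mutant(task, rng))
    Zs, ys, levs, min_others = [], [], [], []
    for s in init_seqs:
        mu, _ = vae.encode_seq(s)
        dec = vae.decode_latent(mu, L)
        res, _ = eval_seq(dec, 0)
        if res is None:
            continue
        Zs.append(mu)
        ys.append(task.scalarize(res.oracle_values))
        levs.append(res.lev)
        min_others.append(min((res.oracle_values[c] for c in task.other_conditions),
                              default=1.0))
    state = SearchState(Z=np.array(Zs, dtype=float), y=np.array(ys),
                     lev=np.array(levs, dtype=float),
                     min_other=np.array(min_others), tr_length=tr_init)
    if latent_scale is None:
        latent_scale = np.maximum(state.Z.std(axis=0), 0.25)

    def best_feasible() -> tuple[int | None, float]:
        feas = (state.lev <= task.edit_budget) & (state.min_other >= task.psi_floor)
        if feas.any():
            pool = np.flatnonzero(feas)
            i = pool[np.argmax(state.y[pool])]
            return int(i), float(state.y[i])
        return None, -np.inf

    max_iters = 3 * (task.oracle_budget // max(batch, 1)) + 20
    it = 0
    stall = 0
    dup_added: dict[str, int] = {}
    kernels = {"obj": None, "lev": None, "floor": None}
    while calls < task.oracle_budget and it < max_iters and stall < 25:
        it += 1
        state.iteration = it
        keep = np.arange(len(state.y))
        if len(keep) > max_gp_points:
            best = np.argsort(state.y)[-max_gp_points // 2:]
            recent = np.arange(len(state.y))[-max_gp_points // 2:]
            keep = np.unique(np.concatenate([best, recent]))
        Z, y = state.Z[keep], state.y[keep]
        # hyperparameters re-optimised periodically, reused in between
        refit = (it - 1) % 5 == 0 or kernels["obj"] is None
        gp_obj = fit_surrogate(Z, y, kernels["obj"], refit)
        gp_lev = fit_surrogate(Z, state.lev[keep], kernels["lev"], refit)
        gp_floor = fit_surrogate(Z, -state.min_other[keep], kernels["floor"], refit)
        kernels = {"obj": gp_obj.kernel_, "lev": gp_lev.kernel_,
                   "floor": gp_floor.kernel_}
        i_best, y_best = best_feasible()
        if i_best is None:
            viol = (np.maximum(state.lev - task.edit_budget, 0)
                    + np.maximum(task.psi_floor - state.min_other, 0))
            i_best = int(np.argmin(viol))
            y_best = float(state.y[i_best])
        center = state.Z[i_best]
        block_dims = getattr(vae.config, "block_latent", None) \
            if getattr(vae.config, "block_size", None) else None
        cand = propose_candidates(
            gp_obj, [(gp_lev, float(task.edit_budget)), (gp_floor, -task.psi_floor)],
            center, state.tr_length, latent_scale, rng, n_candidates, batch,
            anchors=anchor_latents, explore_frac=explore_frac, block_dims=block_dims)
        improved = False
        n_new = 0
        for z in cand:
            seq = vae.decode_latent(z.astype(np.float32), L)
            res, is_new = eval_seq(seq, it)
            if res is None:
                continue
            if not is_new:
                # plateau information: keep at most one extra latent per
                # known sequence so duplicates cannot swamp the surrogate
                if dup_added.get(seq, 0) >= 1:
                    continue
                dup_added[seq] = dup_added.get(seq, 0) + 1
            n_new += is_new
            state.Z = np.vstack([state.Z, z])
            state.y = np.append(state.y, task.scalarize(res.oracle_values))
            state.lev = np.append(state.lev, res.lev)
            state.min_other = np.append(
                state.min_other,
                min((res.oracle_values[c] for c in task.other_conditions), default=1.0))
            feasible = (res.lev <= task.edit_budget
                        and task.floor_ok(res.oracle_values))
            if is_new and feasible and state.y[-1] > y_best + 1e-9:
                improved = True
        if n_new == 0:
            stall += 1
            if stall == 10:  # re-seed the search before giving up
                state.tr_length = tr_init
        else:
            stall = 0
        if n_new <= len(cand) // 2:
            # decoder plateau: most candidates collapsed onto known
            # sequences, widen the search region
            state.tr_length = min(state.tr_length * 1.5, tr_bounds[1])
        if improved:
            state.successes += 1
            state.failures = 0
            if state.successes >= tr_success_tol:
                state.tr_length = min(2 * state.tr_length, tr_bounds[1])
                state.successes = 0
        else:
            state.failures += 1
            state.successes = 0
            if state.failures >= tr_fail_tol:
                state.tr_length /= 2
                state.failures = 0
                if state.tr_length < tr_bounds[0]:
                    state.tr_length = tr_init  # restart on collapse
    return results


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def random_mutation_baseline(
    task: DesignTask,
    oracle: Oracle,
    mer_lengths=(3, 6, 15, 30),
    seed: int = 0,
) -> list[DesignResult]:
    """Random mer substitutions of the start sequence (one per call)."""
    if max(mer_lengths) > len(task.start_sequence):
        raise ValueError("mer length exceeds the sequence length")
    rng = np.random.default_rng(seed)
    results = []
    for i in range(task.oracle_budget):
        seq = _random_mutant(task, rng, mer_lengths)
        results.append(_evaluate(task, oracle, seq, i, "RM"))
    return results


@dataclass
class GaParams:
    population: int = 50
    tournament: int = 3
    mutation_rate: float = 0.01
    crossover: bool = True
    elitism: int = 1
    init_mer_lengths: tuple = (3, 6, 15, 30)


def _repair(seq: str, start: str, tau: int, rng: np.random.Generator) -> str:
    """Revert random edits until the candidate respects the edit budget."""
    s = list(seq)
    diff = [i for i, (a, b) in enumerate(zip(s, start)) if a != b]
    while len(diff) > tau:
        j = diff.pop(int(rng.integers(0, len(diff))))
        s[j] = start[j]
    return "".join(s)


def genetic_algorithm_baseline(
    task: DesignTask,
    oracle: Oracle,
    params: GaParams | None = None,
    seed: int = 0,
) -> list[DesignResult]:
    """Generational GA with tournament selection, single-point crossover,
    per-base mutation and tau-repair; same accounting as the optimizer."""
    params = params or GaParams()
    if task.oracle_budget < params.population:
        raise ValueError("oracle budget smaller than the GA population")
    rng = np.random.default_rng(seed)
    results: list[DesignResult] = []
    calls = 0

    def fitness(res: DesignResult) -> float:
        y = task.scalarize(res.oracle_values)
        if res.lev > task.edit_budget:
            y -= 10.0 * (res.lev - task.edit_budget)
        if not task.floor_ok(res.oracle_values):
            y -= 10.0
        return y

    pop: list[DesignResult] = []
    for _ in range(params.population):
        seq = _random_mutant(task, rng, params.init_mer_lengths)
        res = _evaluate(task, oracle, seq, 0, "GA")
        results.append(res)
        pop.append(res)
        calls += 1
    gen = 0
    while calls < task.oracle_budget:
        gen += 1
        fits = np.array([fitness(r) for r in pop])
        new: list[DesignResult] = [pop[int(np.argmax(fits))]] * params.elitism

        def select() -> str:
            idx = rng.integers(0, len(pop), size=params.tournament)
            return pop[int(idx[np.argmax(fits[idx])])].sequence

        while len(new) < params.population and calls < task.oracle_budget:
            p1, p2 = select(), select()
            if params.crossover and rng.random() < 0.9:
                cut = int(rng.integers(1, len(p1)))
                child = p1[:cut] + p2[cut:]
            else:
                child = p1
            if params.mutation_rate > 0:
                cl = list(child)
                hits = np.flatnonzero(rng.random(len(cl)) < params.mutation_rate)
                for j in hits:
                    cl[j] = BASES[(BASES.index(cl[j]) + int(rng.integers(1, 4))) % 4]
                child = "".join(cl)
            child = _repair(child, task.start_sequence, task.edit_budget, rng)
            res = _evaluate(task, oracle, child, gen, "GA")
            results.append(res)
            new.append(res)
            calls += 1
        pop = new
    return results


def results_table(results: list[DesignResult], seed: int | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"method": r.method, "iteration": r.iteration, "sequence": r.sequence,
               "lev": r.lev, "success": r.success}
        if seed is not None:
            row["seed"] = seed
        row.update({f"psi_{c}": v for c, v in r.oracle_values.items()})
        rows.append(row)
    return pd.DataFrame(rows)
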