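"""Leave-one-out cross-validated fit statistic F_CV.

For each held-out subject s in a cohort of N networks, the model is run
with the optimal parameters of each of the other N-1 subjects (matching
s's edge count and geometry), ``repeats`` times per parameter source to
average over model stochasticity. The mean fit over repeats gives N-1
per-source means; their average is F_CV(s). Smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine, evaluation, metrics
from ._seeds import derive_seed


@dataclass
class Cohort:
    """Per-subject networks and optimized parameters over a shared geometry.

    ``subject_ids`` are stable integer identifiers used in seed
    derivation; permuting subjects together with their ids leaves every
    stochastic run, and hence F_CV, unchanged.
    """

    networks: list[np.ndarray]
    params: list[engine.Params]
    dset: engine.DistanceSet
    subject_ids: list[int] | None = None

    def __post_init__(self):
        if len(self.networks) < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if len(self.params) != len(self.networks):
            missing = len(self.networks) - len(self.params)
            raise ValueError(f"missing optimized parameters for {missing} subject(s)")
        n = self.dset.n_nodes
        self.networks = [metrics.validate_adjacency(A) for A in self.networks]
        if any(A.shape[0] != n for A in self.networks):
            raise ValueError("all cohort networks must match the geometry size")
        for s, p in enumerate(self.params):
            if p is None:
                raise ValueError(f"subject {s} has no optimized parameters")
        if self.subject_ids is None:
            self.subject_ids = list(range(len(self.networks)))
        elif len(set(self.subject_ids)) != len(self.networks):
            raise ValueError("subject_ids must be unique, one per subject")

    @property
    def n_subjects(self) -> int:
        return len(self.networks)


@dataclass(frozen=True)
class FcvResult:
    """Per-subject F_CV and the intermediate per-source mean fits."""

    fcv: np.ndarray                 # (N,)
    per_source_means: list[np.ndarray]  # one (N-1,) vector per subject
    repeats: int
    n_runs: int


def loo_fcv(
    cohort: Cohort,
    spec: engine.ModelSpec,
    repeats: int = 20,
    seed: int = 0,
    constraint: np.ndarray | None = None,
    generator=None,
) -> FcvResult:
    """Leave-one-out cross-validated fit for every subject of a cohort.

    ``generator(spec, params, dset, E, seed, constraint=...)`` defaults
    to :func:`connectogen.engine.grow`; a deterministic stub can be
    injected for accounting checks. Seeds are derived from
    (seed, held-out id, source id, repeat), so results are independent
    of execution order.
    """
    if generator is None:
        def generator(spec, params, dset, E, run_seed, constraint=None):
            return engine.grow(spec, params, dset, E, seed=run_seed,
                               constraint=constraint)

    N = cohort.n_subjects
    fcv = np.empty(N)
    per_source = []
    n_runs = 0
    for s in range(N):
        A_s = cohort.networks[s]
        E_s = int(A_s.sum()) // 2
        means = []
        for src in range(N):
            if src == s:
                continue
            fits = []
            for rep in range(repeats):
                run_seed = derive_seed(
                    seed, cohort.subject_ids[s], cohort.subject_ids[src], rep
                )
                A = generator(spec, cohort.params[src], cohort.dset, E_s,
                              run_seed, constraint=constraint)
                fits.append(
                    evaluation.evaluate_fit(A, A_s, cohort.dset.eval_matrix).max_ks
                )
                n_runs += 1
            means.append(float(np.mean(fits)))
        per_source.append(np.asarray(means))
        fcv[s] = float(np.mean(means))
    return FcvResult(fcv=fcv, per_source_means=per_source, repeats=repeats,
                     n_runs=n_runs)
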