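"""Synthetic gene-regulatory networks with known ground truth.

A linear-Gaussian generative model: TF expression profiles are i.i.d.
standard normal across conditions, and each target gene is a sparse linear
combination of its regulators plus Gaussian noise,

    tg_g(c) = sum_t w(t, g) * tf_t(c) + eps,   eps ~ N(0, noise_sd^2),

with exactly ``regulators_per_tg`` nonzero weights per target, drawn with
random sign and magnitude uniform in [0.5, 2].  The network is bipartite by
default (TFs are never targets), which keeps recovery experiments free of
feedback confounding; ``tf_targets`` adds acyclic TF -> TF edges (each TF
after the first is driven by earlier TFs plus a unit-variance innovation)
and declares TFs as studied targets too.  The emitted gold standard marks
the nonzero-weight pairs as positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .containers import GoldStandard


@dataclass
class SyntheticGRN:
    """A sampled regulator network plus its simulation parameters.

    Defaults describe the reference recovery benchmark: 20 TFs, 100 targets,
    3 regulators per target, 200 conditions, noise sd 0.5, seed 7.
    """

    n_tfs: int = 20
    n_tgs: int = 100
    regulators_per_tg: int = 3
    n_conditions: int = 200
    noise_sd: float = 0.5
    seed: int = 7
    tf_targets: bool = False
    weights: pd.DataFrame = field(default=None, repr=False)
    tf_weights: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.regulators_per_tg > self.n_tfs:
            raise ValueError("regulators_per_tg cannot exceed n_tfs")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.weights is None:
            self.weights = self._draw_weights()
        if self.tf_targets and self.tf_weights is None:
            self.tf_weights = self._draw_tf_weights()

    @property
    def tf_ids(self) -> list:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def tg_ids(self) -> list:
        return [f"G{i + 1:04d}" for i in range(self.n_tgs)]

    def _draw_weights(self) -> pd.DataFrame:
        rng = np.random.default_rng(derive_seed(self.seed, "weights"))
        weights = np.zeros((self.n_tfs, self.n_tgs))
        for j in range(self.n_tgs):
            regulators = rng.choice(self.n_tfs, size=self.regulators_per_tg, replace=False)
            magnitude = rng.uniform(0.5, 2.0, size=self.regulators_per_tg)
            sign = rng.choice([-1.0, 1.0], size=self.regulators_per_tg)
            weights[regulators, j] = magnitude * sign
        return pd.DataFrame(weights, index=self.tf_ids, columns=self.tg_ids)

    def _draw_tf_weights(self) -> pd.DataFrame:
        # acyclic: TF i is regulated only by TFs with smaller index
        rng = np.random.default_rng(derive_seed(self.seed, "tf_weights"))
        weights = np.zeros((self.n_tfs, self.n_tfs))
        for i in range(1, self.n_tfs):
            k = min(self.regulators_per_tg, i)
            regulators = rng.choice(i, size=k, replace=False)
            weights[regulators, i] = rng.uniform(0.5, 2.0, size=k) * rng.choice(
                [-1.0, 1.0], size=k
            )
        return pd.DataFrame(weights, index=self.tf_ids, columns=self.tf_ids)

    def gold_standard(self) -> GoldStandard:
        positives = {
            (tf, tg)
            for tf in self.weights.index
            for tg in self.weights.columns
            if self.weights.at[tf, tg] != 0
        }
        studied_tgs = set(self.weights.columns)
        if self.tf_targets:
            positives |= {
                (a, b)
                for a in self.tf_weights.index
                for b in self.tf_weights.columns
                if self.tf_weights.at[a, b] != 0
            }
            studied_tgs |= set(self.tf_ids)
        return GoldStandard(
            frozenset(positives),
            studied_tfs=frozenset(self.weights.index),
            studied_tgs=frozenset(studied_tgs),
        )


def simulate(grn: SyntheticGRN):
    """Draw one expression matrix from the network; returns (expr, gold).

    The matrix stacks TF rows above target rows (genes x conditions).  The
    draw is fully determined by ``grn.seed``.
    """
    rng = np.random.default_rng(derive_seed(grn.seed, "expression"))
    conditions = [f"C{i + 1:04d}" for i in range(grn.n_conditions)]
    tf_expr = rng.standard_normal((grn.n_tfs, grn.n_conditions))
    if grn.tf_targets:
        w_ff = grn.tf_weights.to_numpy()
        for i in range(1, grn.n_tfs):  # innovations already drawn above
            tf_expr[i] += w_ff[:i, i] @ tf_expr[:i]
    noise = rng.normal(0.0, grn.noise_sd, size=(grn.n_tgs, grn.n_conditions))
    tg_expr = grn.weights.to_numpy().T @ tf_expr + noise
    expr = pd.DataFrame(
        np.vstack([tf_expr, tg_expr]),
        index=grn.tf_ids + grn.tg_ids,
        columns=conditions,
    )
    return expr, grn.gold_standard()


def recovery_experiment(
    grn: SyntheticGRN,
    methods: list,
    scheme: str | None = None,
    ensemble_members: list | None = None,
    config=None,
) -> dict:
    """Run scorers on a simulated matrix and evaluate each against the truth.

    Returns ``{method_name: EvaluationReport}``; when ``scheme`` is given,
    the ensemble of ``ensemble_members`` (default: all methods) is evaluated
    under the key ``"ensemble"``.  Per-method seeds derive from ``grn.seed``.
    """
    from .evaluation import evaluate_scores
    from .inference import MethodConfig, score_links
    from .integration import integrate

    expr, gold = simulate(grn)
    config = config or MethodConfig(seed=derive_seed(grn.seed, "scoring"))
    targets = (grn.tf_ids + grn.tg_ids) if grn.tf_targets else grn.tg_ids
    reports = {}
    matrices = {}
    for method in methods:
        sm = score_links(expr, grn.tf_ids, method, config=config, targets=targets)
        matrices[method] = sm
        reports[method] = evaluate_scores(sm, gold)
    if scheme is not None:
        members = ensemble_members or list(methods)
        ensemble = integrate([matrices[m] for m in members], scheme)
        reports["ensemble"] = evaluate_scores(ensemble.scores, gold)
    return reports
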