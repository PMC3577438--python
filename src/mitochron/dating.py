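"""Strict-clock Bayesian dating on a fixed topology, statsmodels-style.

:class:`ClockDatingModel` couples an alignment (or supermatrix), a rooted
topology and a strict clock whose rate is either fixed (e.g. the insect
mtDNA rate 0.0115 substitutions/site/my) or free with a root calibration
prior (the Drosophila–Anopheles split: Normal with mean 260 mya whose
central 95% mass spans 243–276 mya). ``fit()`` runs a Metropolis–Hastings
sampler over node ages (order-constrained uniform priors), the rate and —
for the dating model — nothing else, and returns a :class:`DatingResults`
carrying traces, node-age posteriors and diagnostics.

A closed-form alternative, :func:`rate_date`, converts a corrected pairwise
distance d into a divergence time d / (2 mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import compress_patterns, tree_log_likelihood
from .substmodels import JC69, SubstitutionModel
from .timetree import TimeTree, TreeNode

__all__ = [
    "CalibrationPrior",
    "ClockModel",
    "ClockDatingModel",
    "DatingResults",
    "rate_date",
    "mcmc_date",
    "effective_sample_size",
]


@dataclass
class CalibrationPrior:
    """Normal prior on the root age (mya), optionally hard-truncated."""

    mean: float = 260.0
    sd: float = 8.42  # so that [243, 276] is ~ the central 95% mass
    bounds: Optional[tuple[float, float]] = (243.0, 276.0)
    truncated: bool = False

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not (lo < self.mean < hi):
                raise ValueError("bounds must bracket the mean")

    def logpdf(self, age: float) -> float:
        if self.truncated and self.bounds is not None:
            lo, hi = self.bounds
            if not (lo <= age <= hi):
                return -np.inf
        z = (age - self.mean) / self.sd
        return -0.5 * z * z - np.log(self.sd)


@dataclass
class ClockModel:
    """Strict molecular clock: one rate for every lineage (subs/site/my)."""

    rate: Optional[float] = 0.0115  # None = free, sampled under a calibration
    mode: str = "strict"

    def __post_init__(self):
        if self.mode != "strict":
            raise ValueError("only the strict clock is implemented")
        if self.rate is not None and self.rate <= 0:
            raise ValueError("rate must be positive")


def rate_date(d: float, rate: float = 0.0115) -> float:
    """Divergence time (mya) from a corrected pairwise distance: d / (2 mu)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return d / (2.0 * rate)


def effective_sample_size(samples: np.ndarray) -> float:
    """Autocorrelation-time ESS (bulk ESS as implemented in ArviZ)."""
    import arviz

    samples = np.asarray(samples, dtype=float)
    if samples.size < 4 or np.allclose(samples, samples[0]):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(arviz.ess(samples))


class _ClockLikelihood:
    """Flattened pruning evaluator for repeated likelihood calls.

    Precomputes the postorder traversal and leaf partials once; ``eval``
    recomputes the likelihood for the current node ages at a given rate.
    A closed-form shortcut covers the two-taxon JC69 case (likelihood
    depends only on the match/mismatch site counts).
    """

    def __init__(self, patterns, model: SubstitutionModel, tree: TimeTree):
        self.model = model
        self.rates = model.category_rates()
        self.freqs = model.freqs
        order = list(tree.postorder())
        self.nodes = [n for n in order if not n.is_leaf]
        self.leaf_partials = {id(n): patterns.partials[n.label]
                              for n in order if n.is_leaf}
        self.counts = patterns.counts
        self.tree = tree

        self._two_taxon_jc = None
        if (
            tree.n_taxa == 2
            and isinstance(model, JC69)
            and model.alpha is None
        ):
            pa = patterns.partials[tree.taxa[0]]
            pb = patterns.partials[tree.taxa[1]]
            unambig = (pa.sum(axis=1) == 1) & (pb.sum(axis=1) == 1)
            if bool(unambig.all()):
                same = (pa.argmax(axis=1) == pb.argmax(axis=1))
                n_same = float(np.dot(same, patterns.counts))
                n_diff = float(patterns.counts.sum() - n_same)
                self._two_taxon_jc = (n_same, n_diff)

    def eval(self, rate: float) -> float:
        if self._two_taxon_jc is not None:
            n_same, n_diff = self._two_taxon_jc
            t = 2.0 * rate * self.tree.root.age
            e = np.exp(-4.0 * t / 3.0)
            p_same = 0.25 * (0.25 + 0.75 * e)
            p_diff = 0.25 * (0.25 - 0.25 * e)
            if p_diff <= 0:
                p_diff = 1e-300
            return n_same * np.log(p_same) + n_diff * np.log(p_diff)

        per_cat = []
        for g in self.rates:
            partials: dict[int, np.ndarray] = dict(self.leaf_partials)
            for node in self.nodes:
                part = None
                for child in node.children:
                    t = max(rate * (node.age - child.age), 0.0) * g
                    P = self.model.pmatrix(t)
                    contrib = partials[id(child)] @ P.T
                    part = contrib if part is None else part * contrib
                partials[id(node)] = part
            lik = partials[id(self.tree.root)] @ self.freqs
            per_cat.append(np.log(np.maximum(lik, 1e-300)))
        if len(per_cat) == 1:
            logs = per_cat[0]
        else:
            stack = np.stack(per_cat)
            mx = stack.max(axis=0)
            logs = mx + np.log(np.exp(stack - mx).mean(axis=0))
        return float(np.dot(logs, self.counts))


def _node_label(node: TreeNode) -> str:
    if node.parent is None:
        return "root"
    reps = []
    for child in node.children:
        tips = [l.label for l in _tips_below(child)]
        reps.append(min(tips))
    return "mrca_" + "_".join(sorted(reps))


def _tips_below(node: TreeNode) -> list[TreeNode]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


class ClockDatingModel:
    """Bayesian strict-clock node-age model on a fixed rooted topology.

    Parameters
    ----------
    sequences : dict[str, str] or Supermatrix
        Aligned sequences keyed by taxon (taxa must match the topology tips).
    topology : TimeTree
        Fixed rooted topology; its node ages initialize the chain.
    subst_model : SubstitutionModel, optional
        Substitution model for the likelihood (default JC69).
    clock : ClockModel
        Fixed-rate clock, or free rate (``rate=None``) with a calibration.
    calibration : CalibrationPrior, optional
        Root-age prior; required when the clock rate is free. Without a
        calibration the root prior is uniform on [0, root_max].
    root_max : float
        Upper bound of the diffuse uniform root prior (mya).
    likelihood_off : bool
        Sample from the prior only (prior-recovery diagnostics).
    """

    def __init__(
        self,
        sequences,
        topology: TimeTree,
        subst_model: Optional[SubstitutionModel] = None,
        clock: Optional[ClockModel] = None,
        calibration: Optional[CalibrationPrior] = None,
        root_max: float = 1000.0,
        likelihood_off: bool = False,
    ):
        if hasattr(sequences, "taxa") and hasattr(sequences, "sequences"):
            sequences = dict(zip(sequences.taxa, sequences.sequences))
        self.topology = topology.copy()
        self.subst_model = subst_model if subst_model is not None else JC69()
        self.clock = clock if clock is not None else ClockModel()
        self.calibration = calibration
        self.root_max = root_max
        self.likelihood_off = likelihood_off

        if self.clock.rate is None and calibration is None:
            raise ValueError("a free clock rate requires a calibration prior")
        if not likelihood_off:
            missing = set(self.topology.taxa) - set(sequences)
            if missing:
                raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
            self.patterns = compress_patterns(
                {t: sequences[t] for t in self.topology.taxa}
            )
            self._evaluator = _ClockLikelihood(
                self.patterns, self.subst_model, self.topology
            )
        else:
            self.patterns = None
            self._evaluator = None

        self._internal = self.topology.internal_nodes()
        self._labels = [_node_label(n) for n in self._internal]
        self._init_ages = [n.age for n in self._internal]

    # -- target density ----------------------------------------------------

    def _log_prior(self, rate: float) -> float:
        root_age = self.topology.root.age
        if self.calibration is not None:
            lp = self.calibration.logpdf(root_age)
        else:
            lp = 0.0 if 0 < root_age <= self.root_max else -np.inf
        if self.clock.rate is None:
            # log-uniform prior on the free rate
            lp += -np.log(rate)
        return lp

    def _log_likelihood(self, rate: float) -> float:
        if self.likelihood_off:
            return 0.0
        return self._evaluator.eval(rate)

    # -- sampler -----------------------------------------------------------

    def fit(
        self,
        chain_length: int = 200_000,
        sample_every: int = 100,
        burnin: float = 0.10,
        n_runs: int = 3,
        seed: Optional[int] = None,
        root_step: float = 2.0,
        rate_step: float = 0.2,
    ) -> "DatingResults":
        """Run ``n_runs`` independent chains and pool post-burn-in samples.

        Proposals: a uniform redraw of one internal node age within its
        parent/children bounds (symmetric), a Gaussian walk on the root age,
        and — when the rate is free — a multiplicative rate move.
        """
        runs = []
        for r in range(n_runs):
            run_seed = None if seed is None else seed + 1000 * r
            runs.append(
                self._run_chain(chain_length, sample_every, run_seed,
                                root_step, rate_step)
            )
        return DatingResults(self, runs, burnin, chain_length, sample_every)

    def _run_chain(self, chain_length, sample_every, seed, root_step, rate_step):
        rng = np.random.default_rng(seed)
        # reset to the initial ages so every chain starts identically
        for n, age in zip(self._internal, self._init_ages):
            n.age = age
        tree = self.topology
        internal = self._internal
        root = tree.root
        rate = self.clock.rate if self.clock.rate is not None else 0.01
        free_rate = self.clock.rate is None

        lp = self._log_prior(rate)
        if not np.isfinite(lp):
            # start the root inside the prior's support
            root.age = (
                self.calibration.mean if self.calibration is not None
                else 0.5 * self.root_max
            )
            for n in internal:
                if n is not root and n.age >= root.age:
                    n.age = root.age * 0.5
            lp = self._log_prior(rate)
        ll = self._log_likelihood(rate)

        non_root = [n for n in internal if n.parent is not None]
        n_moves = len(non_root) + 1 + (1 if free_rate else 0)
        records = []
        accepted = 0
        check_at = min(5000, chain_length)
        for it in range(chain_length):
            move = rng.integers(n_moves)
            if move < len(non_root):
                node = non_root[move]
                lo = max((c.age for c in node.children), default=0.0)
                hi = node.parent.age
                if hi > lo:
                    old = node.age
                    node.age = lo + (hi - lo) * rng.random()
                    new_lp = self._log_prior(rate)
                    new_ll = self._log_likelihood(rate)
                    if np.log(rng.random() + 1e-300) < (new_lp + new_ll) - (lp + ll):
                        lp, ll = new_lp, new_ll
                        accepted += 1
                    else:
                        node.age = old
            elif move == len(non_root):
                old = root.age
                prop = old + rng.normal(0.0, root_step)
                lo = max(c.age for c in root.children)
                if prop <= lo or prop > self.root_max:
                    pass  # out of support: reject
                else:
                    root.age = prop
                    new_lp = self._log_prior(rate)
                    new_ll = self._log_likelihood(rate)
                    if np.log(rng.random() + 1e-300) < (new_lp + new_ll) - (lp + ll):
                        lp, ll = new_lp, new_ll
                        accepted += 1
                    else:
                        root.age = old
            else:
                old_rate = rate
                factor = np.exp(rate_step * (rng.random() - 0.5))
                prop_rate = old_rate * factor
                new_lp = self._log_prior(prop_rate)
                new_ll = self._log_likelihood(prop_rate)
                # Hastings factor for the scale move
                log_h = np.log(factor)
                if np.log(rng.random() + 1e-300) < (
                    (new_lp + new_ll) - (lp + ll) + log_h
                ):
                    rate = prop_rate
                    lp, ll = new_lp, new_ll
                    accepted += 1

            if it + 1 == check_at and accepted == 0:
                raise RuntimeError(
                    "no proposals accepted in the diagnostic window; "
                    "adjust root_step/rate_step"
                )
            if (it + 1) % sample_every == 0:
                rec = {lab: n.age for lab, n in zip(self._labels, internal)}
                rec["rate"] = rate
                rec["log_likelihood"] = ll
                rec["log_prior"] = lp
                records.append(rec)
        df = pd.DataFrame.from_records(records)
        df.attrs["acceptance"] = accepted / max(chain_length, 1)
        df.attrs["seed"] = seed
        return df


class DatingResults:
    """Posterior traces and node-age summaries from a ClockDatingModel fit."""

    def __init__(self, model: ClockDatingModel, runs: list[pd.DataFrame],
                 burnin: float, chain_length: int, sample_every: int):
        self.model = model
        self.runs = runs
        self.burnin = burnin
        self.chain_length = chain_length
        self.sample_every = sample_every
        cut = int(np.floor(len(runs[0]) * burnin))
        self.trace = pd.concat(
            [r.iloc[cut:] for r in runs], ignore_index=True
        )

    @property
    def node_labels(self) -> list[str]:
        return list(self.model._labels)

    def posterior_mean(self, label: str = "root") -> float:
        return float(self.trace[label].mean())

    def credible_interval(self, label: str = "root",
                          level: float = 0.95) -> tuple[float, float]:
        """Central credible interval (quantile-based, not HPD)."""
        a = (1.0 - level) / 2.0
        lo, hi = self.trace[label].quantile([a, 1.0 - a])
        return float(lo), float(hi)

    def ess(self, label: str = "root") -> float:
        return effective_sample_size(self.trace[label].to_numpy())

    def summary(self, ess_warn: float = 200.0) -> pd.DataFrame:
        """Node-age table: posterior mean, central 95% CI, ESS per node.

        Columns mirror the usual divergence-time report (node, mean mya,
        95% credibility interval); a warning is issued for any ESS at or
        below ``ess_warn``.
        """
        if len(self.trace) < 100:
            raise ValueError("need at least 100 post-burn-in samples")
        rows = []
        labels = self.node_labels + (["rate"] if self.model.clock.rate is None else [])
        for lab in labels:
            mean = self.posterior_mean(lab)
            lo, hi = self.credible_interval(lab)
            ess = self.ess(lab)
            if ess <= ess_warn:
                warnings.warn(f"ESS for {lab} is {ess:.0f} (<= {ess_warn:.0f})")
            rows.append(
                {"node": lab, "mean": mean, "ci_2.5%": lo, "ci_97.5%": hi,
                 "ess": ess}
            )
        return pd.DataFrame(rows)

    def per_run_ess(self, label: str = "root") -> list[float]:
        cut = int(np.floor(len(self.runs[0]) * self.burnin))
        return [
            effective_sample_size(r[label].to_numpy()[cut:]) for r in self.runs
        ]

    def to_tsv(self, handle) -> None:
        self.trace.to_csv(handle, sep="\t", index=False)

    def plot_posterior(self, label: str = "root", bins: int = 50, ax=None):
        """Histogram of a node-age posterior with mean and 95% CI marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        samples = self.trace[label]
        ax.hist(samples, bins=bins, density=True, alpha=0.7)
        lo, hi = self.credible_interval(label)
        ax.axvline(samples.mean(), ls="-", color="k")
        for x in (lo, hi):
            ax.axvline(x, ls="--", color="k")
        ax.set_xlabel(f"{label} age (mya)")
        ax.set_ylabel("posterior density")
        return ax


def mcmc_date(
    sequences,
    topology: TimeTree,
    clock: Optional[ClockModel] = None,
    calibration: Optional[CalibrationPrior] = None,
    subst_model: Optional[SubstitutionModel] = None,
    chain_length: int = 200_000,
    sample_every: int = 100,
    burnin: float = 0.10,
    n_runs: int = 1,
    seed: Optional[int] = None,
    likelihood_off: bool = False,
    root_max: float = 1000.0,
    **kwargs,
) -> DatingResults:
    """Functional wrapper: build a ClockDatingModel and fit it."""
    model = ClockDatingModel(
        sequences, topology, subst_model=subst_model, clock=clock,
        calibration=calibration, root_max=root_max,
        likelihood_off=likelihood_off,
    )
    return model.fit(
        chain_length=chain_length, sample_every=sample_every, burnin=burnin,
        n_runs=n_runs, seed=seed, **kwargs,
    )


def summarize(results: DatingResults) -> pd.DataFrame:
    """Node-age summary table (posterior mean, 95% CI, ESS per node)."""
    return results.summary()
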