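"""Multi-rater consensus: infer a Standard Reference from noisy annotations.

Dermoscopic pattern presence has no biopsy-level ground truth; it is judged
subjectively, with known low inter-rater agreement.  This module
consolidates the votes of several raters into a single Standard Reference
(SR) with a two-class latent-truth EM model fitted independently per
pattern: each pattern has an unknown prevalence, each rater an unknown
per-pattern sensitivity and specificity, and votes are conditionally
independent given the latent truth (the binary Dawid–Skene model).  The
E-step computes per-image posteriors by Bayes' rule; the M-step re-estimates
prevalence and rater confusion parameters from the posteriors.  A
majority-vote baseline is provided for comparison.

Missing votes (NaN) are skipped in both steps; missingness is assumed
ignorable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .patterns import N_PATTERNS

_CLIP = 1e-6  # keep M-step estimates off the {0, 1} boundary


def majority_vote(votes, tie_rule: str = "positive") -> np.ndarray:
    """Per-cell majority over raters; ties resolved by ``tie_rule``.

    Parameters
    ----------
    votes : array of shape (n_raters, n_images, n_patterns)
        Binary votes; NaN marks a missing vote.
    tie_rule : {"positive", "negative"}
        Label assigned when 1-votes and 0-votes are equally many.
    """
    votes = np.asarray(votes, dtype=float)
    if tie_rule not in ("positive", "negative"):
        raise ValueError("tie_rule must be 'positive' or 'negative'")
    present = ~np.isnan(votes)
    if not present.any(axis=0).all():
        raise ValueError("every (image, pattern) cell needs >= 1 vote")
    ones = np.nansum(votes, axis=0)
    zeros = present.sum(axis=0) - ones
    out = (ones > zeros).astype(int)
    if tie_rule == "positive":
        out[ones == zeros] = 1
    return out


def estep_posterior(votes_1d, sensitivity, specificity, prevalence) -> float:
    """One-image, one-pattern posterior P(truth=1 | votes) by Bayes' rule.

    Exposes the E-step with *frozen* parameters: ``votes_1d`` holds one vote
    per rater (NaN = missing), ``sensitivity``/``specificity`` one value per
    rater.  Useful for closed-form verification and diagnostics.
    """
    v = np.asarray(votes_1d, dtype=float)
    se = np.asarray(sensitivity, dtype=float)
    sp = np.asarray(specificity, dtype=float)
    keep = ~np.isnan(v)
    v, se, sp = v[keep], se[keep], sp[keep]
    log_a = np.log(prevalence) + np.sum(
        v * np.log(se) + (1 - v) * np.log(1 - se)
    )
    log_b = np.log(1 - prevalence) + np.sum(
        v * np.log(1 - sp) + (1 - v) * np.log(sp)
    )
    m = max(log_a, log_b)
    return float(np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m)))


@dataclass
class ConsensusResult:
    """Fitted consensus: posteriors, hard SR labels, rater profiles, trace."""

    posterior: np.ndarray          # (n_images, n_patterns), NaN if unestimable
    sr_labels: np.ndarray          # (n_images, n_patterns) binary
    prevalence: np.ndarray         # (n_patterns,)
    sensitivity: np.ndarray        # (n_raters, n_patterns)
    specificity: np.ndarray        # (n_raters, n_patterns)
    loglik_trace: np.ndarray       # summed across patterns, padded per pattern
    per_pattern_traces: list[np.ndarray]
    converged: np.ndarray          # (n_patterns,) bool
    n_iter: np.ndarray             # (n_patterns,) int
    estimable: np.ndarray          # (n_patterns,) bool


class DawidSkeneConsensus(BaseEstimator):
    """Per-pattern binary Dawid–Skene EM consensus, scikit-learn style.

    Parameters
    ----------
    tol : float
        Stop a pattern's EM when the absolute log-likelihood improvement
        falls below this.
    max_iter : int
        Iteration cap per pattern.
    init : {"majority", "uniform"}
        Initial posterior: hard majority vote (ties positive) or flat 0.5.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : (n_images, n_patterns) posterior P(truth=1 | votes)
    labels_ : hard SR labels, ``posterior_ >= 0.5``
    prevalence_, sensitivity_, specificity_ : model parameters
    loglik_traces_ : list of per-pattern log-likelihood sequences
    converged_, n_iter_, estimable_ : per-pattern fit status
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 init: str = "majority"):
        self.tol = tol
        self.max_iter = max_iter
        self.init = init

    def fit(self, votes, y=None):
        votes = np.asarray(votes, dtype=float)
        if votes.ndim != 3:
            raise ValueError("votes must have shape (raters, images, patterns)")
        if votes.shape[1] == 0:
            raise ValueError("no images to fit")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.init not in ("majority", "uniform"):
            raise ValueError("init must be 'majority' or 'uniform'")
        n_raters, n_images, n_patterns = votes.shape

        self.posterior_ = np.full((n_images, n_patterns), np.nan)
        self.prevalence_ = np.full(n_patterns, np.nan)
        self.sensitivity_ = np.full((n_raters, n_patterns), np.nan)
        self.specificity_ = np.full((n_raters, n_patterns), np.nan)
        self.loglik_traces_ = []
        self.converged_ = np.zeros(n_patterns, dtype=bool)
        self.n_iter_ = np.zeros(n_patterns, dtype=int)
        self.estimable_ = np.ones(n_patterns, dtype=bool)

        for j in range(n_patterns):
            v = votes[:, :, j]  # (raters, images), NaN = missing
            if np.isnan(v).all():
                self.estimable_[j] = False
                self.loglik_traces_.append(np.array([]))
                continue
            mu, trace, se, sp, pi, conv, it = self._fit_pattern(v)
            self.posterior_[:, j] = mu
            self.prevalence_[j] = pi
            self.sensitivity_[:, j] = se
            self.specificity_[:, j] = sp
            self.loglik_traces_.append(trace)
            self.converged_[j] = conv
            self.n_iter_[j] = it

        with np.errstate(invalid="ignore"):
            self.labels_ = np.where(
                np.isnan(self.posterior_), 0, (self.posterior_ >= 0.5)
            ).astype(int)
        return self

    def _fit_pattern(self, v):
        present = ~np.isnan(v)
        v0 = np.nan_to_num(v)
        if self.init == "majority":
            mu = majority_vote(v[:, :, None], tie_rule="positive")[:, 0].astype(float)
        else:
            # A perfectly flat posterior is an exact fixed point of EM (all
            # raters then satisfy sensitivity = 1 - specificity, so the
            # E-step carries no evidence); break the symmetry with a tiny
            # pull toward each image's mean vote.
            with np.errstate(invalid="ignore"):
                vote_mean = np.nanmean(v, axis=0)
            mu = 0.5 + 1e-3 * (np.nan_to_num(vote_mean, nan=0.5) - 0.5)

        trace = []
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # M-step: prevalence and per-rater confusion from posteriors
            pi = np.clip(mu.mean(), _CLIP, 1 - _CLIP)
            denom_pos = (present * mu).sum(axis=1)
            denom_neg = (present * (1 - mu)).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                se = (present * v0 * mu).sum(axis=1) / denom_pos
                sp = (present * (1 - v0) * (1 - mu)).sum(axis=1) / denom_neg
            se = np.clip(np.nan_to_num(se, nan=0.5), _CLIP, 1 - _CLIP)
            sp = np.clip(np.nan_to_num(sp, nan=0.5), _CLIP, 1 - _CLIP)

            # E-step: Bayes posteriors and observed-data log-likelihood
            log_a = np.log(pi) + (
                present * (v0 * np.log(se)[:, None]
                           + (1 - v0) * np.log(1 - se)[:, None])
            ).sum(axis=0)
            log_b = np.log(1 - pi) + (
                present * (v0 * np.log(1 - sp)[:, None]
                           + (1 - v0) * np.log(sp)[:, None])
            ).sum(axis=0)
            m = np.maximum(log_a, log_b)
            ll = float((m + np.log(np.exp(log_a - m) + np.exp(log_b - m))).sum())
            mu = 1.0 / (1.0 + np.exp(log_b - log_a))
            trace.append(ll)
            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll
        return mu, np.asarray(trace), se, sp, pi, converged, it

    def result(self) -> ConsensusResult:
        """Bundle the fitted attributes into a :class:`ConsensusResult`."""
        n_pat = self.posterior_.shape[1]
        lengths = [len(t) for t in self.loglik_traces_ if len(t)]
        total = np.zeros(max(lengths) if lengths else 0)
        for t in self.loglik_traces_:
            if len(t) == 0:
                continue
            padded = np.concatenate([t, np.full(len(total) - len(t), t[-1])])
            total += padded
        return ConsensusResult(
            posterior=self.posterior_,
            sr_labels=self.labels_,
            prevalence=self.prevalence_,
            sensitivity=self.sensitivity_,
            specificity=self.specificity_,
            loglik_trace=total,
            per_pattern_traces=self.loglik_traces_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            estimable=self.estimable_,
        )


def em_consensus(
    annotations,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: str = "majority",
) -> ConsensusResult:
    """Functional wrapper: fit :class:`DawidSkeneConsensus` on a vote tensor."""
    est = DawidSkeneConsensus(tol=tol, max_iter=max_iter, init=init)
    est.fit(annotations)
    return est.result()
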