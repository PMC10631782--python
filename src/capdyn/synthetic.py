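"""Synthetic two-group cohorts of Markov-state BOLD runs.

The generator emulates the structure that whole-brain CAP analysis assumes:
each scan is a sequence of transient brain states, each state has a fixed
whole-brain spatial pattern, and a frame expresses its state's pattern plus
noise. States follow a first-order Markov chain whose transition matrix
differs between the two groups, so occupancy, entry rate and dwell time all
differ at once. A clinical score (MMSE-like, clipped to [0, 30]) is coupled
linearly to the subject's true state occupancies.

Latent states are emitted directly per frame, with no hemodynamic
convolution: CAP analysis operates on individual frames and the downstream
pipeline models no hemodynamics either. All spatial/temporal realism beyond
this (motion, physiology, anatomy) is explicitly out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    BoldRun,
    ScoreModel,
    StateSequence,
    SyntheticCohort,
    SyntheticCohortConfig,
    ValidationError,
    check_row_stochastic,
)

__all__ = [
    "sample_state_sequence",
    "render_bold",
    "generate_cohort",
    "make_templates",
    "persistent_transition_matrix",
    "stationary_distribution",
    "default_cohort_config",
    "DEFAULT_PI_NC",
    "DEFAULT_SHIFTED_STATE",
    "DEFAULT_OCCUPANCY_SHIFT",
]

#: Stationary occupancies of the control group's chain, one per latent
#: state, in decreasing order (so ground-truth state 1 is the most
#: frequent control state).
DEFAULT_PI_NC = np.array([0.25, 0.19, 0.16, 0.12, 0.11, 0.09, 0.08])

#: 1-based latent state whose occupancy is shifted in the patient group and
#: whose occupancy drives the clinical score.
DEFAULT_SHIFTED_STATE = 1

#: Occupancy reduction of the shifted state in the patient group.
DEFAULT_OCCUPANCY_SHIFT = 0.15


def sample_state_sequence(
    p: np.ndarray,
    n_frames: int,
    initial_dist: np.ndarray,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "sim",
    tr: float = 3.0,
) -> StateSequence:
    """Sample a first-order Markov chain of 1-based state labels.

    Parameters
    ----------
    p : (K, K) row-stochastic matrix
        ``p[i, j]`` is the probability of moving from state ``i+1`` to
        state ``j+1``.
    n_frames : int
        Sequence length (>= 1).
    initial_dist : length-K probability vector
        Distribution of the first label.
    seed : int or Generator
        Randomness source; an int is wrapped in ``default_rng``.
    """
    p = check_row_stochastic(p)
    k = p.shape[0]
    if n_frames < 1:
        raise ValidationError(f"n_frames must be >= 1, got {n_frames}")
    d = np.asarray(initial_dist, dtype=float)
    if d.size != k or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
        raise ValidationError("initial_dist must be a length-K distribution")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # inverse-CDF sampling against precomputed cumulative rows: one uniform
    # draw per frame keeps long chains cheap and reproducible
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_frames)
    labels = np.empty(n_frames, dtype=int)
    state = int(np.searchsorted(np.cumsum(d / d.sum()), u[0], side="right"))
    state = min(state, k - 1)
    labels[0] = state + 1
    for t in range(1, n_frames):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, k - 1)
        labels[t] = state + 1
    return StateSequence(subject_id=subject_id, labels=labels, tr=tr)


def render_bold(
    seq: StateSequence,
    templates: np.ndarray,
    noise_sd: float,
    tr: float,
    seed: int | np.random.Generator,
) -> BoldRun:
    """Render a state sequence into a voxel x time BOLD matrix.

    Frame ``t`` equals ``templates[label_t - 1]`` plus iid Gaussian noise of
    standard deviation ``noise_sd`` in every voxel.
    """
    templates = np.asarray(templates, dtype=float)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    k = templates.shape[0]
    if np.any(seq.labels > k):
        raise ValidationError(
            f"sequence labels up to {seq.labels.max()} exceed {k} templates"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = templates[seq.labels - 1].T.copy()  # (n_voxels, T)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return BoldRun(data=data, tr=tr, subject_id=seq.subject_id, band_tag="unfiltered")


def make_templates(
    k: int, n_voxels: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Near-orthogonal unit-variance spatial patterns.

    Gaussian vectors are orthonormalized by QR and then standardized per
    pattern (mean 0, sd 1 across voxels), leaving them orthogonal up to
    O(1/sqrt(n_voxels)) terms.
    """
    if n_voxels < k:
        raise ValidationError("n_voxels must be >= k")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = rng.standard_normal((n_voxels, k))
    q, _ = np.linalg.qr(g)
    t = q.T  # (k, n_voxels), orthonormal rows
    t = t - t.mean(axis=1, keepdims=True)
    t = t / t.std(axis=1, keepdims=True)
    return t


def persistent_transition_matrix(pi: np.ndarray, persistence: float = 0.3) -> np.ndarray:
    """Chain with stationary distribution ``pi`` and tunable dwell time.

    ``P = persistence * I + (1 - persistence) * 1 pi^T``; the stationary
    distribution is ``pi`` for any persistence in [0, 1), and the expected
    dwell time of state k is ``1 / (1 - P_kk)`` frames.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValidationError("pi must be a strictly positive distribution")
    if not (0 <= persistence < 1):
        raise ValidationError("persistence must lie in [0, 1)")
    k = pi.size
    return persistence * np.eye(k) + (1.0 - persistence) * np.tile(pi, (k, 1))


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    p = check_row_stochastic(p)
    vals, vecs = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def shifted_occupancy(
    pi: np.ndarray, state: int, delta: float
) -> np.ndarray:
    """Reduce state ``state`` (1-based) by ``delta``, redistributing
    the mass proportionally over the remaining states."""
    pi = np.asarray(pi, dtype=float)
    i = state - 1
    if not (0 <= i < pi.size):
        raise ValidationError(f"state {state} out of range")
    if pi[i] - delta <= 0:
        raise ValidationError("shift would make the occupancy nonpositive")
    out = pi.copy()
    out[i] -= delta
    others = np.arange(pi.size) != i
    out[others] *= (1.0 - out[i]) / pi[others].sum()
    return out / out.sum()


def default_cohort_config(
    seed: int,
    *,
    n_per_group: int = 20,
    n_voxels: int = 2000,
    n_frames: int = 130,
    k_true: int = 7,
    noise_sd: float = 0.3,
    tr: float = 3.0,
    persistence: float = 0.3,
    occupancy_shift: float = DEFAULT_OCCUPANCY_SHIFT,
    shifted_state: int = DEFAULT_SHIFTED_STATE,
) -> SyntheticCohortConfig:
    """Study-default cohort: 2 x 20 subjects, T=130 at TR=3 s, N=2000
    voxels, K=7 near-orthogonal templates, noise sd 0.3.

    The patient group's chain shifts the occupancy of ``shifted_state``
    down by ``occupancy_shift``; the MMSE-like score is
    ``20 + 30 * occupancy(shifted_state) + N(0, 1)``, clipped to [0, 30],
    so patients score lower and the score-occupancy correlation has a known
    positive sign.
    """
    if k_true == DEFAULT_PI_NC.size:
        pi_nc = DEFAULT_PI_NC.copy()
    else:
        raw = np.linspace(1.5, 0.5, k_true)
        pi_nc = raw / raw.sum()
    pi_ad = shifted_occupancy(pi_nc, shifted_state, occupancy_shift)
    templates = make_templates(k_true, n_voxels, np.random.default_rng(seed))
    coefficients = np.zeros(k_true)
    coefficients[shifted_state - 1] = 30.0
    return SyntheticCohortConfig(
        n_subjects_per_group={"AD": n_per_group, "NC": n_per_group},
        templates=templates,
        transition_by_group={
            "AD": persistent_transition_matrix(pi_ad, persistence),
            "NC": persistent_transition_matrix(pi_nc, persistence),
        },
        noise_sd=noise_sd,
        score_model=ScoreModel(intercept=20.0, coefficients=coefficients, residual_sd=1.0),
        seed=seed,
        tr=tr,
        n_frames=n_frames,
    )


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full cohort: runs, hidden sequences and phenotypes.

    Deterministic given ``config.seed``. Subject ids are
    ``<group>-<index>``; the phenotype table carries subject_id, group,
    sex, age, MMSE and CDR. Sex is drawn uniformly, age from N(74, 7^2)
    truncated at [55, 95], CDR from the group-typical range; the MMSE-like
    score follows ``config.score_model`` applied to the subject's empirical
    state occupancies and is clipped to [0, 30].
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_true
    runs: list[BoldRun] = []
    seqs: list[StateSequence] = []
    rows: list[dict] = []
    for group in config.groups:
        p = config.transition_by_group[group]
        init = (
            config.initial_dist
            if config.initial_dist is not None
            else stationary_distribution(p)
        )
        for i in range(config.n_subjects_per_group[group]):
            sid = f"{group}-{i + 1:03d}"
            seq = sample_state_sequence(
                p, config.n_frames, init, rng, subject_id=sid, tr=config.tr
            )
            seq.band_tag = "unfiltered"
            run = render_bold(seq, config.templates, config.noise_sd, config.tr, rng)
            occ = np.bincount(seq.labels - 1, minlength=k) / config.n_frames
            score = (
                config.score_model.intercept
                + float(config.score_model.coefficients @ occ)
                + rng.normal(0.0, config.score_model.residual_sd)
            )
            cdr = 0.0 if group == "NC" else float(np.round(rng.uniform(0.5, 1.0) * 2) / 2)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "age": float(np.clip(rng.normal(74.0, 7.0), 55.0, 95.0)),
                    "MMSE": float(np.clip(score, 0.0, 30.0)),
                    "CDR": cdr,
                }
            )
            runs.append(run)
            seqs.append(seq)
    phenotypes = pd.DataFrame(rows)
    return SyntheticCohort(
        runs=runs,
        ground_truth_sequences=seqs,
        phenotypes=phenotypes,
        config=config,
    )
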