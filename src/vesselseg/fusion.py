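"""Modal fusion and GMM/FCM clustering — the tail of the multimodal pipeline.

The four per-modality segmentations are merged into one probability map
(mean, weighted mean, or majority vote), and the fused per-pixel foreground
score is then clustered two ways:

* a two-component 1-D Gaussian mixture fitted by EM (log-likelihood is
  non-decreasing at every iteration, asserted), and
* fuzzy C-means with fuzzifier m > 1, minimizing Σ u_ik^m · |x_i − c_k|²
  (objective non-increasing at every iteration, asserted).

Each clustering's "foreground" cluster is the one with the higher mean fused
score.  The final mask averages the GMM foreground responsibility and the FCM
foreground membership and thresholds at 0.5, with ties resolving to
background (conservative for small-vessel false positives).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


class FusionError(ValueError):
    pass


# Variances live on the [0, 1] score scale: a component sd below 1% of that
# scale models quantization noise rather than class structure, and letting a
# component collapse onto a point spike sends every off-spike value to the
# other component.  The floor keeps responsibilities meaningful.
_VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class FusionConfig:
    """Fusion rule for the four per-modality probability maps."""

    rule: str = "mean"  # mean | weighted | majority
    weights: tuple[float, ...] | None = None

    def validate(self, n_maps: int) -> None:
        if self.rule not in ("mean", "weighted", "majority"):
            raise FusionError(f"unknown fusion rule {self.rule!r}")
        if self.rule == "weighted":
            if self.weights is None or len(self.weights) != n_maps:
                raise FusionError(f"weighted rule needs exactly {n_maps} weights")
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise FusionError("weights must be nonnegative and sum to 1")


@dataclass
class GMMParams:
    """1-D Gaussian mixture state for EM."""

    n_components: int = 2
    means: np.ndarray | None = None
    variances: np.ndarray | None = None
    mixing_weights: np.ndarray | None = None
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    n_init: int = 4
    covariance: str = "full"  # "full": per-component variances; "tied": pooled


@dataclass
class FCMParams:
    """Fuzzy C-means state."""

    n_clusters: int = 2
    fuzzifier: float = 2.0
    centers: np.ndarray | None = None
    membership: np.ndarray | None = None
    max_iter: int = 100
    tol: float = 1e-7
    seed: int = 0
    n_init: int = 4


def fuse_modalities(maps: Sequence[np.ndarray], config: FusionConfig | None = None) -> np.ndarray:
    """Merge per-modality (K, H, W) probability maps per the configured rule.

    Output is renormalized so per-pixel class probabilities sum to 1.
    """
    config = config or FusionConfig()
    if len(maps) != 4:
        raise FusionError(f"expected 4 modality maps, got {len(maps)}")
    arrs = [np.asarray(m, dtype=float) for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise FusionError(f"modality map shapes differ: {sorted(shapes)}")
    config.validate(len(arrs))
    stack = np.stack(arrs)  # (4, K, H, W)
    if config.rule == "mean":
        fused = stack.mean(axis=0)
    elif config.rule == "weighted":
        w = np.asarray(config.weights, dtype=float)
        fused = np.einsum("m...,m->...", stack, w)
    else:  # majority vote on per-map argmax, expressed as class indicators
        votes = stack.argmax(axis=1)  # (4, H, W)
        K = stack.shape[1]
        fused = np.stack([(votes == k).mean(axis=0) for k in range(K)])
    total = fused.sum(axis=0, keepdims=True)
    return fused / np.clip(total, 1e-12, None)


# ---------------------------------------------------------------------------
# GMM via EM
# ---------------------------------------------------------------------------

def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ center choice on 1-D data."""
    centers = [values[rng.integers(len(values))]]
    for _ in range(1, k):
        d2 = np.min([(values - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(values[rng.integers(len(values))])
            continue
        centers.append(values[rng.choice(len(values), p=d2 / total)])
    return np.sort(np.asarray(centers, dtype=float))


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def gmm_fit(values: np.ndarray, params: GMMParams | None = None) -> tuple[GMMParams, np.ndarray, list[float]]:
    """EM fit of a 1-D Gaussian mixture.

    Runs ``n_init`` seeded k-means++ initializations (or a single run when
    explicit starting means are supplied) and keeps the solution with the
    highest final log-likelihood.  Returns the fitted parameters, per-value
    responsibilities ``(n, k)`` and the winning run's log-likelihood
    trajectory (one entry per iteration, non-decreasing).  Components whose
    variance collapses are floored at a small epsilon with a logged warning.
    """
    params = params or GMMParams()
    x = np.asarray(values, dtype=float).ravel()
    k = params.n_components
    if k < 1:
        raise FusionError("n_components must be >= 1")
    if len(np.unique(x)) < k:
        raise FusionError(f"need at least {k} distinct values to fit {k} components")
    rng = np.random.default_rng(params.seed)
    if params.means is not None:
        inits = [np.asarray(params.means, dtype=float).copy()]
    else:
        inits = [_kmeanspp_init(x, k, rng) for _ in range(max(1, params.n_init))]
    best: tuple | None = None
    for means0 in inits:
        result = _gmm_em_once(x, params, means0)
        if best is None or result[2][-1] > best[2][-1]:
            best = result
    return best


def _gmm_em_once(
    x: np.ndarray, params: GMMParams, means0: np.ndarray
) -> tuple[GMMParams, np.ndarray, list[float]]:
    k = params.n_components
    means = means0.copy()
    var0 = max(x.var(), _VAR_FLOOR)
    variances = (
        np.asarray(params.variances, dtype=float).copy()
        if params.variances is not None
        else np.full(k, var0)
    )
    mix = (
        np.asarray(params.mixing_weights, dtype=float).copy()
        if params.mixing_weights is not None
        else np.full(k, 1.0 / k)
    )

    loglik_history: list[float] = []
    resp = np.full((len(x), k), 1.0 / k)
    for _ in range(params.max_iter):
        # E-step
        log_comp = np.stack(
            [np.log(np.clip(mix[j], 1e-300, None)) + _log_gauss(x, means[j], variances[j]) for j in range(k)],
            axis=1,
        )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        loglik = float(lse.sum())
        if loglik_history:
            assert loglik >= loglik_history[-1] - 1e-7, "EM log-likelihood decreased"
        resp = np.exp(log_comp - lse[:, None])
        converged = len(loglik_history) > 0 and abs(loglik - loglik_history[-1]) < params.tol
        loglik_history.append(loglik)
        if converged:
            break
        # M-step
        nk = resp.sum(axis=0)
        mix = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / np.clip(nk, 1e-300, None)
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / np.clip(nk, 1e-300, None)
        if params.covariance == "tied":
            # homoscedastic model: one pooled variance; the responsibility
            # crossover is then monotone between the means (LDA-like), which
            # is the behavior wanted when the mixture models a threshold
            variances = np.full(k, (nk * variances).sum() / len(x))
        if (variances < _VAR_FLOOR).any():
            logger.warning("GMM component variance collapsed; flooring at %g", _VAR_FLOOR)
            variances = np.maximum(variances, _VAR_FLOOR)

    fitted = GMMParams(
        n_components=k,
        means=means,
        variances=variances,
        mixing_weights=mix,
        max_iter=params.max_iter,
        tol=params.tol,
        seed=params.seed,
    )
    return fitted, resp, loglik_history


# ---------------------------------------------------------------------------
# fuzzy C-means
# ---------------------------------------------------------------------------

def fcm_fit(values: np.ndarray, params: FCMParams | None = None) -> tuple[FCMParams, list[float]]:
    """Alternating FCM optimization on 1-D values.

    Runs ``n_init`` seeded k-means++ initializations (or one run from
    explicit centers) and keeps the lowest final objective.  Memberships
    u_ik ∈ [0, 1] sum to 1 per value; a value coinciding with a center
    receives membership 1 to (the first of) its coincident centers.  Returns
    fitted parameters (centers + membership) and the winning run's objective
    trajectory (non-increasing, asserted).
    """
    params = params or FCMParams()
    x = np.asarray(values, dtype=float).ravel()
    c = params.n_clusters
    m = params.fuzzifier
    if c < 2:
        raise FusionError("n_clusters must be >= 2")
    if m <= 1:
        raise FusionError("fuzzifier must be > 1")
    rng = np.random.default_rng(params.seed)
    if params.centers is not None:
        inits = [np.asarray(params.centers, dtype=float).copy()]
    else:
        inits = [_kmeanspp_init(x, c, rng) for _ in range(max(1, params.n_init))]
    best: tuple | None = None
    for centers0 in inits:
        result = _fcm_once(x, params, centers0)
        if best is None or result[1][-1] < best[1][-1]:
            best = result
    return best


def _fcm_once(x: np.ndarray, params: FCMParams, centers0: np.ndarray) -> tuple[FCMParams, list[float]]:
    c = params.n_clusters
    m = params.fuzzifier
    centers = centers0.copy()

    def memberships(centers: np.ndarray) -> np.ndarray:
        d2 = (x[:, None] - centers[None, :]) ** 2  # (n, c)
        zero = d2 < 1e-300
        u = np.zeros_like(d2)
        any_zero = zero.any(axis=1)
        if any_zero.any():
            first = zero[any_zero].argmax(axis=1)
            u[np.flatnonzero(any_zero), first] = 1.0
        rest = ~any_zero
        if rest.any():
            ratio = d2[rest][:, :, None] / d2[rest][:, None, :]  # (n', c, c)
            u[rest] = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
        return u

    def objective(u: np.ndarray, centers: np.ndarray) -> float:
        return float((u**m * (x[:, None] - centers[None, :]) ** 2).sum())

    u = memberships(centers)
    obj_history = [objective(u, centers)]
    for _ in range(params.max_iter):
        um = u**m
        den = um.sum(axis=0)
        num = (um * x[:, None]).sum(axis=0)
        # a cluster with no members keeps its previous center
        centers = np.where(den > 1e-300, num / np.maximum(den, 1e-300), centers)
        u = memberships(centers)
        obj = objective(u, centers)
        assert obj <= obj_history[-1] + 1e-9, "FCM objective increased"
        converged = abs(obj_history[-1] - obj) < params.tol
        obj_history.append(obj)
        if converged:
            break

    order = np.argsort(centers)
    fitted = FCMParams(
        n_clusters=c,
        fuzzifier=m,
        centers=centers[order],
        membership=u[:, order],
        max_iter=params.max_iter,
        tol=params.tol,
        seed=params.seed,
    )
    return fitted, obj_history


# ---------------------------------------------------------------------------
# combination and the full pipeline
# ---------------------------------------------------------------------------

def estimate_fusion_weights(dice_scores: Sequence[float], floor: float = 1e-3) -> tuple[float, ...]:
    """Per-modality fusion weights from held-out Dice, by the log-odds rule.

    A modality with error e = 1 − Dice gets weight ∝ log((1 − e)/e) — the
    classical weighted-majority combination rule — so accurate modalities
    dominate the fused map while near-chance ones contribute little.  Errors
    are floored to keep weights finite; weights are clipped at zero and
    normalized to sum to 1.
    """
    e = np.clip(1.0 - np.asarray(dice_scores, dtype=float), floor, 1 - floor)
    w = np.clip(np.log((1.0 - e) / e), 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    return tuple(float(v) for v in w)


def fit_fusion_weights(
    prob_maps: Sequence[Sequence[np.ndarray]],
    truths: Sequence[np.ndarray],
    step: float = 0.05,
    tolerance: float = 0.0,
) -> tuple[float, ...]:
    """Stacked fusion: pick simplex weights maximizing held-out fused Dice.

    ``prob_maps[i][m]`` is modality m's (2, H, W) probability map for probe
    image i, ``truths[i]`` the matching ground-truth mask.  All weight
    vectors on a simplex grid of the given step are scored by the mean Dice
    of the weighted fused map thresholded at 0.5; the best grid point wins.
    Among combos within ``tolerance`` of the best (exact ties by default)
    the most diversified — closest to uniform — is preferred, keeping the
    choice deterministic.  Learning the combiner on held-out predictions is
    the classical stacked-generalization recipe; with correlated experts of
    unequal skill it concentrates weight where uniform averaging would
    dilute.
    """
    W, mean_dice = _grid_threshold_dice(prob_maps, truths, step)
    n_mod = W.shape[1]
    top = mean_dice >= mean_dice.max() - tolerance
    spread = ((W - 1.0 / n_mod) ** 2).sum(axis=1)
    spread[~top] = np.inf
    best = int(spread.argmin())
    return tuple(float(v) for v in W[best])


def _grid_threshold_dice(
    prob_maps: Sequence[Sequence[np.ndarray]],
    truths: Sequence[np.ndarray],
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Dice of the 0.5-thresholded weighted fusion for every grid combo."""
    if len(prob_maps) == 0 or len(prob_maps) != len(truths):
        raise FusionError("need equal, non-zero numbers of probe maps and truths")
    n_mod = len(prob_maps[0])
    n = int(round(1.0 / step))
    combos: list[list[int]] = []

    def _compose(prefix, remaining, slots):
        if slots == 1:
            combos.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            _compose(prefix + [v], remaining - v, slots - 1)

    _compose([], n, n_mod)
    W = np.asarray(combos, dtype=float) / n  # (C, n_mod)

    dice_sum = np.zeros(len(W))
    for maps, truth in zip(prob_maps, truths):
        P = np.stack([np.asarray(m, dtype=float)[1].ravel() for m in maps])  # (n_mod, Npix)
        y = np.asarray(truth).ravel().astype(bool)
        F = W @ P  # (C, Npix)
        pred = F > 0.5
        tp = (pred & y).sum(axis=1)
        denom = pred.sum(axis=1) + y.sum()
        dice_sum += np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), 1.0)
    return W, dice_sum / len(prob_maps)


def fit_fusion_weights_end_to_end(
    prob_maps: Sequence[Sequence[np.ndarray]],
    truths: Sequence[np.ndarray],
    gmm: GMMParams | None = None,
    fcm: FCMParams | None = None,
    step: float = 0.05,
    top_k: int = 20,
) -> tuple[float, ...]:
    """Stacked fusion scored through the *deployed* decision rule.

    The fast 0.5-threshold grid search ranks all simplex weight vectors;
    the ``top_k`` candidates (plus the per-modality unit vectors and the
    uniform vector) are then re-scored by the Dice of the full
    GMM+FCM-clustered mask on the probe images, and the best wins (ties to
    the most diversified).  Scoring the combiner on the decision rule that
    will actually be applied avoids choosing weights that look good under
    a plain threshold but lose through the clustering stage.
    """
    W, mean_dice = _grid_threshold_dice(prob_maps, truths, step)
    n_mod = W.shape[1]
    order = np.argsort(-mean_dice)[:top_k]
    candidates = {tuple(W[i]) for i in order}
    candidates.update(tuple(np.eye(n_mod)[m]) for m in range(n_mod))
    candidates.add(tuple(np.full(n_mod, 1.0 / n_mod)))

    shapes = [np.asarray(t).shape for t in truths]
    best_w, best_score, best_spread = None, -np.inf, np.inf
    for w in sorted(candidates):
        cfg = FusionConfig(rule="weighted", weights=tuple(w))
        score = 0.0
        for maps, truth, shape in zip(prob_maps, truths, shapes):
            fused = fuse_modalities(maps, cfg)
            mask = cluster_fused_scores(fused, gmm, fcm)
            y = np.asarray(truth).astype(bool)
            denom = mask.sum() + y.sum()
            score += (2.0 * (mask.astype(bool) & y).sum() / denom) if denom else 1.0
        score /= len(prob_maps)
        spread = float(((np.asarray(w) - 1.0 / n_mod) ** 2).sum())
        if score > best_score + 1e-12 or (abs(score - best_score) <= 1e-12 and spread < best_spread):
            best_w, best_score, best_spread = tuple(float(v) for v in w), score, spread
    return best_w


def _foreground_column(scores: np.ndarray, soft: np.ndarray) -> int:
    """Column of ``soft`` whose weighted mean fused score is highest.

    On exactly equal means the lowest qualifying column index wins
    (numpy argmax convention), with a warning — deterministic either way.
    """
    weighted_means = (soft * scores[:, None]).sum(axis=0) / np.clip(soft.sum(axis=0), 1e-300, None)
    best = int(weighted_means.argmax())
    if (weighted_means == weighted_means[best]).sum() > 1:
        warnings.warn("ambiguous cluster/class matching (equal means); tie broken deterministically")
    return best


def combine_clusterings(
    gmm_resp: np.ndarray,
    fcm_membership: np.ndarray,
    scores: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Average GMM responsibility and FCM membership, threshold at 0.5.

    ``scores`` are the fused per-pixel foreground scores used to decide which
    cluster is "foreground" in each clustering (highest mean score).  A pixel
    scoring exactly 0.5 resolves to background.  A cluster only counts as
    foreground if its mean fused score exceeds 0.5: on a degenerate input
    (e.g. a vessel-free image) the clusterings merely partition background
    noise, and the result is then all-background rather than an arbitrary
    half of the noise.
    """
    if gmm_resp.shape[0] != fcm_membership.shape[0] or gmm_resp.shape[0] != scores.size:
        raise FusionError("clusterings must cover the same pixels")
    fg_scores = []
    for soft in (gmm_resp, fcm_membership):
        col = _foreground_column(scores, soft)
        col_mean = (soft[:, col] * scores).sum() / np.clip(soft[:, col].sum(), 1e-300, None)
        fg_scores.append(soft[:, col] if col_mean > 0.5 else np.zeros(soft.shape[0]))
    fg_score = 0.5 * (fg_scores[0] + fg_scores[1])
    mask = (fg_score > 0.5).astype(np.uint8)
    return mask.reshape(shape)


#: Anchored starting means/centers for clustering fused foreground scores.
#: The fused score is a calibrated probability (background near 0, vessel
#: near 1), so clustering refines this known bimodal structure rather than
#: searching for an arbitrary one; anchoring below/above the 0.5 decision
#: point keeps the two components attached to their semantic classes.
_SCORE_ANCHORS = (0.25, 0.75)


def cluster_fused_scores(
    fused: np.ndarray,
    gmm: GMMParams | None = None,
    fcm: FCMParams | None = None,
) -> np.ndarray:
    """GMM + FCM clustering of a fused (2, H, W) probability map into a mask.

    Unless the caller supplies explicit starting means/centers, both
    clusterings start from the fixed score anchors rather than data-driven
    seeding: on heavily class-imbalanced score distributions a
    likelihood-driven restart can model substructure of the dominant
    background instead of the background/vessel split.
    """
    import dataclasses as _dc

    fg = np.asarray(fused, dtype=float)[1]
    scores = fg.ravel()
    gmm = gmm or GMMParams(covariance="tied")
    fcm = fcm or FCMParams()
    if gmm.means is None and gmm.n_components == 2:
        gmm = _dc.replace(gmm, means=np.array(_SCORE_ANCHORS))
    if fcm.centers is None and fcm.n_clusters == 2:
        fcm = _dc.replace(fcm, centers=np.array(_SCORE_ANCHORS))
    _, resp, _ = gmm_fit(scores, gmm)
    fitted_fcm, _ = fcm_fit(scores, fcm)
    return combine_clusterings(resp, fitted_fcm.membership, scores, fg.shape)


def run_multimodal_pipeline(
    image: np.ndarray,
    models: Sequence,
    filter_config=None,
    fusion_config: FusionConfig | None = None,
    gmm: GMMParams | None = None,
    fcm: FCMParams | None = None,
    stride: int = 2,
    return_intermediates: bool = False,
):
    """Full multimodal segmentation of one image.

    Stages: modality-stack expansion → per-modality CNN segmentation →
    fusion → GMM + FCM clustering of the fused foreground score → final mask.
    ``models`` supplies one trained patch CNN per modality channel.  Any
    stage failure is re-raised with the stage name attached.
    """
    from vesselseg.cnn import segment_cnn
    from vesselseg.filters import build_modality_stack

    if len(models) != 4:
        raise FusionError(f"expected 4 per-modality models, got {len(models)}")

    stage = "modality_stack"
    try:
        stack = build_modality_stack(image, filter_config)
        stage = "segment_cnn"
        maps = [segment_cnn(stack.channels[i], models[i], stride=stride) for i in range(4)]
        stage = "fuse_modalities"
        fused = fuse_modalities(maps, fusion_config)
        stage = "clustering"
        mask = cluster_fused_scores(fused, gmm, fcm)
    except Exception as exc:
        raise RuntimeError(f"multimodal pipeline failed in stage '{stage}': {exc}") from exc
    if return_intermediates:
        return mask, {"stack": stack, "modality_maps": maps, "fused": fused}
    return mask
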