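"""Ground-truth linear observer for parameter-recovery simulations.

The decision model mirrors the estimator exactly: on each trial the
observer projects the stimulus cochleogram S onto an internal template
beta*, adds a bias c*, passes the decision variable through an inverse
logit, and answers 'ga' with that probability:

    p(ga) = logit^-1(gain * <S, beta*> + c*)

Internal noise is absorbed into the logistic through the gain — a high
gain means a nearly deterministic observer, a low gain a guessy one —
so the simulated responses come from the same likelihood family that
the template estimator fits, making parameter recovery well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ObserverSpec:
    """A linear template observer (ground-truth beta*, c*)."""

    template: np.ndarray  # weight map on the cochleogram grid
    bias: float
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def decision_probability(self, cochleogram_values: np.ndarray) -> float:
        s = np.asarray(cochleogram_values)
        if s.shape != self.template.shape:
            raise ValueError(
                f"cochleogram shape {s.shape} does not match template "
                f"shape {self.template.shape}")
        return float(expit(self.gain * float(np.vdot(s, self.template))
                           + self.bias))

    def respond(self, cochleogram_values: np.ndarray, rng) -> int:
        """Bernoulli response: 1 = 'ga', 0 = 'da'."""
        return int(rng.random() < self.decision_probability(cochleogram_values))


def ideal_template_from_targets(target_cochleograms, labels) -> np.ndarray:
    """Class-contrast template: mean(ga cochleograms) - mean(da cochleograms).

    ``labels`` gives the response class (0 = da, 1 = ga) of each
    cochleogram.  The result is normalized to unit Frobenius norm and is
    antisymmetric under label swap.
    """
    arrs = [np.asarray(getattr(c, "values", c), dtype=np.float64)
            for c in target_cochleograms]
    labels = np.asarray(labels)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValueError("need at least one cochleogram per class")
    ga = np.mean([a for a, l in zip(arrs, labels) if l == 1], axis=0)
    da = np.mean([a for a, l in zip(arrs, labels) if l == 0], axis=0)
    diff = ga - da
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("classes are identical; template undefined")
    return diff / norm


def centered_bias(template: np.ndarray, gain: float, ref_cochleograms,
                  ref_labels) -> float:
    """Bias cancelling the mean template projection over reference stimuli.

    Centering on the stimuli the observer will actually see matters:
    noisy mixes carry broadband noise energy and a renormalization
    factor, so their projections are systematically offset from the
    clean targets'.  The returned bias puts the midpoint of the two
    class-mean projections at a decision variable of zero.
    """
    arrs = [np.asarray(getattr(c, "values", c), dtype=np.float64)
            for c in ref_cochleograms]
    proj = np.array([float(np.vdot(a, template)) for a in arrs])
    labels = np.asarray(ref_labels)
    mid = 0.5 * (proj[labels == 1].mean() + proj[labels == 0].mean())
    return -gain * mid


def matched_observer(target_cochleograms, labels, gain: float,
                     reference_cochleograms=None, reference_labels=None,
                     zero_mean: bool = False, seed: int = 0) -> ObserverSpec:
    """Observer with the ideal contrast template and a centered bias.

    The template is the clean-target class contrast; the bias is centered
    on ``reference_cochleograms`` (e.g. noisy mixes at the task's
    operating SNR) when given, otherwise on the clean targets.  With
    ``zero_mean`` the template is mean-subtracted (then renormalized),
    which makes the decision variable insensitive to the global energy
    level of the stimulus — a crude level normalization that keeps the
    observer's criterion stable as the staircase moves the SNR.
    """
    template = ideal_template_from_targets(target_cochleograms, labels)
    if zero_mean:
        template = template - template.mean()
        template /= np.linalg.norm(template)
    if reference_cochleograms is None:
        reference_cochleograms, reference_labels = target_cochleograms, labels
    bias = centered_bias(template, gain, reference_cochleograms,
                         reference_labels)
    return ObserverSpec(template=template, bias=bias, gain=gain, seed=seed)


def perturbed_observer(base: ObserverSpec, heterogeneity: float, seed: int,
                       reference_cochleograms=None, reference_labels=None,
                       zero_mean: bool = False) -> ObserverSpec:
    """An individual observer: base template plus a smooth random distortion.

    ``heterogeneity`` is the norm of the added smooth perturbation
    relative to the (unit-norm) base template; the result is renormalized
    and, when a reference set is given, the bias is recentred for the
    new template.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal(base.template.shape), 1.5)
    if zero_mean:
        noise = noise - noise.mean()
    noise *= heterogeneity / np.linalg.norm(noise)
    template = base.template + noise
    if zero_mean:
        template = template - template.mean()
    template = template / np.linalg.norm(template)
    if reference_cochleograms is not None:
        bias = centered_bias(template, base.gain, reference_cochleograms,
                             reference_labels)
    else:
        bias = base.bias
    return ObserverSpec(template=template, bias=bias, gain=base.gain,
                        seed=seed)


def calibrate_gain(accuracy_fn, target_accuracy: float = 0.5 ** (1 / 3),
                   gain_lo: float = 0.5, gain_hi: float = 500.0,
                   n_steps: int = 10) -> float:
    """Bisect on simulated accuracy to find the gain hitting a target level.

    ``accuracy_fn(gain)`` must return the simulated proportion of correct
    responses at the probe SNR for an observer with that gain; accuracy
    is monotone nondecreasing in gain (higher gain = less internal
    noise), so geometric bisection applies.
    """
    lo, hi = gain_lo, gain_hi
    for _ in range(n_steps):
        mid = float(np.sqrt(lo * hi))
        if accuracy_fn(mid) < target_accuracy:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_pixel_trials(observer: ObserverSpec, class_means, n_trials: int,
                          pixel_noise_sd: float, seed: int = 0):
    """Generate trials directly on the cochleogram grid (no audio path).

    Each trial draws a class uniformly, forms S = class_mean + sd * N(0, I)
    on the pixel grid — emulating the noisy-stimulus cochleogram — and
    queries the observer.  Returns (design matrix, responses, classes);
    used for fast, large-n parameter-recovery studies of the estimator.
    """
    rng = np.random.default_rng(seed)
    means = [np.asarray(getattr(c, "values", c), dtype=np.float64)
             for c in class_means]
    shape = means[0].shape
    n_px = means[0].size
    classes = rng.integers(len(means), size=n_trials)
    X = np.empty((n_trials, n_px))
    responses = np.empty(n_trials, dtype=int)
    for i, k in enumerate(classes):
        s = means[k] + pixel_noise_sd * rng.standard_normal(shape)
        X[i] = s.ravel()
        responses[i] = observer.respond(s, rng)
    return X, responses, classes
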