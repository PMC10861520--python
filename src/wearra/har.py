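"""Human activity recognition with hidden-Markov smoothing.

Raw wrist acceleration is cut into fixed 30-s epochs, summarised into simple
time/frequency features, classified with a multinomial logistic model, and the
resulting per-epoch class posteriors are decoded with a first-order HMM so the
predicted activity sequence is temporally coherent.  Per-epoch predictions are
otherwise independent, so without the HMM the sequence carries no information
epoch-to-epoch.

The window classifier is a transparent stand-in for any epoch-level posterior
source; the HMM layer only consumes posteriors, so a deep network could be
substituted without touching the decoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .synthetic import ActivitySequence, RawTriaxialStream

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class HmmParams:
    classes: tuple[str, ...]
    pi: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K), row-stochastic
    pseudocount: float = 0.0

    def validate(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")


# ---------------------------------------------------------------------------
# windowing and features
# ---------------------------------------------------------------------------

def window_stream(stream: RawTriaxialStream, epoch_len_s: float = 30.0) -> list[np.ndarray]:
    """Split a uniform stream into half-open [t, t+epoch) windows.

    The trailing partial window is dropped.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    n_per = int(round(stream.sample_rate_hz * epoch_len_s))
    n = stream.samples.shape[0]
    n_win = n // n_per
    return [stream.samples[i * n_per:(i + 1) * n_per] for i in range(n_win)]


def extract_window_features(window: np.ndarray, sample_rate_hz: float = 30.0) -> np.ndarray:
    """Deterministic per-epoch summary of a raw tri-axial window.

    Magnitude statistics (mean/sd/percentiles), per-axis means, zero-crossing
    rate of the mean-removed magnitude, and band power in 0.5-3 Hz and 3-8 Hz.
    """
    if window.size == 0:
        raise ValueError("empty window")
    if not np.isfinite(window).all():
        raise ValueError("non-finite samples in window")
    mag = np.linalg.norm(window, axis=1)
    centred = mag - mag.mean()
    zcr = float(np.mean(np.abs(np.diff(np.signbit(centred).astype(np.int8)))))
    feats = [
        mag.mean(), mag.std(),
        *np.percentile(mag, [10, 50, 90]),
        *window.mean(axis=0),
        zcr,
        _band_power(centred, sample_rate_hz, 0.5, 3.0),
        _band_power(centred, sample_rate_hz, 3.0, 8.0),
    ]
    return np.asarray(feats, dtype=float)


def _band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    nperseg = min(x.size, 256)
    f, pxx = signal.welch(x, fs=fs, nperseg=nperseg)
    band = (f >= lo) & (f < min(hi, fs / 2))
    return float(np.trapezoid(pxx[band], f[band])) if band.any() else 0.0


def featurize_stream(stream: RawTriaxialStream, epoch_len_s: float = 30.0) -> np.ndarray:
    """Feature matrix (n_epochs, n_features) for a raw stream."""
    wins = window_stream(stream, epoch_len_s)
    if not wins:
        return np.empty((0, 11))
    return np.vstack([extract_window_features(w, stream.sample_rate_hz) for w in wins])


# ---------------------------------------------------------------------------
# window classifier (stand-in posterior source)
# ---------------------------------------------------------------------------

class WindowClassifier:
    """Standardised multinomial logistic classifier over window features."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000):
        self._pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, max_iter=max_iter),
        )
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WindowClassifier":
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("window classifier needs at least 2 classes")
        self._pipe.fit(X, y)
        self.classes_ = self._pipe[-1].classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._pipe.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pipe.predict(X)


def fit_window_classifier(X: np.ndarray, y: np.ndarray, **kwargs) -> WindowClassifier:
    return WindowClassifier(**kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# HMM estimation and decoding
# ---------------------------------------------------------------------------

def estimate_hmm(sequences: list[np.ndarray], classes: tuple[str, ...],
                 pseudocount: float = 1.0) -> HmmParams:
    """Estimate transition matrix and prior from labelled sequences.

    A[i, j] = (count(i->j) + pseudocount) / (count(i->.) + K * pseudocount);
    the prior is the marginal class frequency (sequences are few but long, so
    initial-state frequencies would be poorly estimated).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    K = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((K, K))
    marginal = np.zeros(K)
    for seq in sequences:
        codes = np.asarray([index[c] for c in seq]) if seq.dtype.kind in "OU" \
            else np.asarray(seq, dtype=int)
        np.add.at(marginal, codes, 1.0)
        if codes.size > 1:
            np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
    rows = counts.sum(axis=1)
    if pseudocount == 0 and (rows == 0).any():
        raise ValueError("class never observed as a source state and "
                         "pseudocount is 0: transition row degenerate")
    A = (counts + pseudocount) / (rows + K * pseudocount)[:, None]
    pi = marginal + pseudocount
    pi = pi / pi.sum()
    return HmmParams(classes=tuple(classes), pi=pi, transition=A, pseudocount=pseudocount)


def viterbi_decode(posteriors: np.ndarray, hmm: HmmParams,
                   scaled_likelihood: bool = True) -> np.ndarray:
    """Maximum a posteriori state path through per-epoch class posteriors.

    With ``scaled_likelihood`` (default) the emission score for class c at
    epoch t is posterior_t(c) / pi(c) — the scaled-likelihood convention that
    restores generative semantics when the classifier's class prior is not
    uniform.  Raw posteriors are used otherwise.  All arithmetic is in log
    space with probabilities floored at 1e-12; Viterbi ties break toward the
    lower class index.

    Returns the integer state path (codes into ``hmm.classes``).
    """
    hmm.validate()
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != len(hmm.classes):
        raise ValueError("posterior matrix must be (T, K) over the HMM classes")
    T, K = post.shape
    if T == 0:
        return np.empty(0, dtype=int)
    if (post.max(axis=1) <= 0).any():
        warnings.warn("epoch with all-zero posterior; numeric floor applied")
    emis = np.maximum(post, PROB_FLOOR)
    if scaled_likelihood:
        emis = emis / np.maximum(hmm.pi, PROB_FLOOR)[None, :]
    log_emis = np.log(emis)
    log_A = np.log(np.maximum(hmm.transition, PROB_FLOOR))
    log_pi = np.log(np.maximum(hmm.pi, PROB_FLOOR))

    delta = log_pi + log_emis[0]
    back = np.empty((T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, None] + log_A  # (from, to)
        # argmax over sources; np.argmax takes the first (lowest index) on ties
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + log_emis[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_score(path: np.ndarray, posteriors: np.ndarray, hmm: HmmParams,
                   scaled_likelihood: bool = True) -> float:
    """Log score of a specific state path (same convention as the decoder)."""
    emis = np.maximum(np.asarray(posteriors, dtype=float), PROB_FLOOR)
    if scaled_likelihood:
        emis = emis / np.maximum(hmm.pi, PROB_FLOOR)[None, :]
    log_emis = np.log(emis)
    log_A = np.log(np.maximum(hmm.transition, PROB_FLOOR))
    log_pi = np.log(np.maximum(hmm.pi, PROB_FLOOR))
    s = log_pi[path[0]] + log_emis[0, path[0]]
    for t in range(1, len(path)):
        s += log_A[path[t - 1], path[t]] + log_emis[t, path[t]]
    return float(s)


def decode_sequence(posteriors: np.ndarray, hmm: HmmParams, participant_id: str,
                    epoch_len_s: int = 30, epoch_start_s: float = 0.0,
                    scaled_likelihood: bool = True) -> ActivitySequence:
    """Viterbi-decode posteriors into an :class:`ActivitySequence`."""
    path = viterbi_decode(posteriors, hmm, scaled_likelihood=scaled_likelihood)
    return ActivitySequence(participant_id, epoch_start_s, epoch_len_s,
                            hmm.classes, path.astype(np.int16))


def simulate_noisy_posteriors(true_codes: np.ndarray, n_classes: int,
                              correct_prob: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Emulate an epoch classifier of known accuracy.

    For each epoch an observed class is drawn equal to the truth with
    probability ``correct_prob`` (uniform error otherwise); the returned
    posterior puts ``correct_prob`` on the observed class and spreads the rest
    uniformly — the independent per-epoch behaviour HMM smoothing corrects.
    """
    T = true_codes.size
    observed = true_codes.copy()
    flip = rng.random(T) >= correct_prob
    n_flip = int(flip.sum())
    if n_flip:
        offs = rng.integers(1, n_classes, size=n_flip)
        observed[flip] = (observed[flip] + offs) % n_classes
    post = np.full((T, n_classes), (1.0 - correct_prob) / (n_classes - 1))
    post[np.arange(T), observed] = correct_prob
    return post
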