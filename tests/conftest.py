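import numpy as np
import pytest

from gliopatch import SyntheticConfig, gen_slide


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-scale config for image-tier tests (6x6 grid of 128-px blocks)."""
    return SyntheticConfig(patches_per_slide=16, patch_size=128, seed=0)


@pytest.fixture(scope="session")
def small_slide(small_cfg):
    """One generated slide plus its ground truth."""
    return gen_slide(small_cfg, "GBM", seed=7)


def silhouette_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Direct O(n^2) mean silhouette; singleton clusters contribute 0."""
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    labels = np.asarray(labels)
    values = []
    for i in range(X.shape[0]):
        same = labels == labels[i]
        same_others = same.copy()
        same_others[i] = False
        if not same_others.any():
            values.append(0.0)
            continue
        a = D[i][same_others].mean()
        b = min(
            D[i][labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        values.append((b - a) / max(a, b))
    return float(np.mean(values))


def auc_pair_counting(y: np.ndarray, scores: np.ndarray) -> float:
    """Brute-force AUC: concordant pairs count 1, ties count 1/2."""
    pos = scores[np.asarray(y, dtype=bool)]
    neg = scores[~np.asarray(y, dtype=bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def otsu_oracle(hist: np.ndarray) -> int:
    """Exhaustive search over all splits for the between-class-variance argmax.

    Uses exact rational arithmetic (sigma_b = w0*w1*(mu0-mu1)^2 via Fractions)
    so near-ties are resolved deterministically toward the smallest threshold.
    """
    from fractions import Fraction

    counts = [int(round(v)) for v in np.asarray(hist)]
    total = sum(counts)
    best_t, best_v = None, Fraction(-1)
    for t in range(len(counts)):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(sum(i * c for i, c in enumerate(counts[: t + 1])), w0)
        mu1 = Fraction(
            sum(i * c for i, c in enumerate(counts) if i > t), w1
        )
        v = Fraction(w0, total) * Fraction(w1, total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v = v
            best_t = t
    return best_t
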