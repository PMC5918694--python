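"""Independent reference implementations used only to check the package.

These deliberately use the most direct formulation available -- exhaustive
pairwise counting for ranking metrics, full-batch proximal gradient descent
for the penalized logistic objective -- and share no code with the package
paths they verify.
"""

import numpy as np


def pairwise_auroc(scores, labels) -> float:
    """AUROC by exhaustive positive-negative pair concordance (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("needs both classes")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_by_hand(scores, labels) -> float:
    """Average precision: precision at each positive's rank, averaged.

    Ranks by descending score; assumes no tied scores (callers ensure it).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores)
    y = labels[order]
    precisions = []
    hits = 0
    for rank, label in enumerate(y, start=1):
        if label == 1:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def proximal_gradient_elastic_net(
    X, y, alpha, l1_ratio, iters=20000, tol=1e-12
) -> tuple[np.ndarray, float]:
    """Full-batch proximal gradient descent (ISTA) on
    mean logistic loss + alpha*(l1*||w||_1 + (1-l1)/2*||w||_2^2),
    intercept unpenalized.  Deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    # Lipschitz constant of the smooth part: ||X||^2 / (4n) + alpha*(1-l1)
    lipschitz = np.linalg.norm(X, 2) ** 2 / (4.0 * n) + alpha * (1.0 - l1_ratio)
    step = 1.0 / lipschitz
    shrink = step * alpha * l1_ratio
    for _ in range(iters):
        z = X @ w + b
        prob = 1.0 / (1.0 + np.exp(-z))
        grad_w = X.T @ (prob - y) / n + alpha * (1.0 - l1_ratio) * w
        grad_b = float((prob - y).mean())
        w_new = w - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - shrink, 0.0)
        b_new = b - step * grad_b
        if np.max(np.abs(w_new - w)) < tol and abs(b_new - b) < tol:
            w, b = w_new, b_new
            break
        w, b = w_new, b_new
    return w, b
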