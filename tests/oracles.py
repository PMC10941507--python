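"""Independent reference implementations used only to cross-check the package.

These deliberately take the slow, literal route (explicit loops, a
non-symmetric eigensolver) so they share no code path with the
implementations they verify.
"""

import numpy as np
import scipy.linalg


def kl_direct(mass1, mass2):
    """KL divergence by explicit summation over grid points."""
    total = 0.0
    for a, b in zip(mass1, mass2):
        total += a * np.log(a / b)
    return total


def symmetric_kl_direct(mass1, mass2):
    return (kl_direct(mass1, mass2) + kl_direct(mass2, mass1)) / 2.0


def bh_stepup(pvals, q):
    """Benjamini-Hochberg step-up from its textbook definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    # adjusted p: monotone min over tail of p_(i) * m / i
    adj_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj_sorted[i] = running
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, reject


def diffusion_scores_dense(W, alpha=0.5, n_components=10):
    """Diffusion-map scores via the non-symmetric Markov operator.

    Builds P = row-normalized D^-a W D^-a explicitly and uses the
    general (non-symmetric) eigensolver, then applies unit-norm column
    scaling and the multiscale lambda/(1-lambda) factor.
    """
    W = np.asarray(W, float)
    d = W.sum(axis=1)
    Wa = W / np.outer(d**alpha, d**alpha)
    P = Wa / Wa.sum(axis=1)[:, None]
    evals, evecs = scipy.linalg.eig(P)
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam = evals[1 : n_components + 1]
    psi = evecs[:, 1 : n_components + 1]
    psi = psi / np.linalg.norm(psi, axis=0)
    return psi * (lam / (1.0 - lam)), lam


def align_signs(A, B):
    """Flip columns of A to match the sign of the matching column in B."""
    A = A.copy()
    for c in range(A.shape[1]):
        if np.dot(A[:, c], B[:, c]) < 0:
            A[:, c] = -A[:, c]
    return A
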