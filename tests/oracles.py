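"""Independent reference implementations used only by the tests.

These are deliberately written from the underlying mathematics (closed
forms, normal equations, textbook metric definitions) rather than through
the package's own code paths, so each test compares two independent routes
to the same quantity.
"""

import numpy as np


def single_sphere_potential(sensor, src_pos, moment, R, sigma):
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Summing the Legendre expansion of the dipole potential plus its
    boundary correction in closed form (generating functions of P_n and
    P_n^1) gives, with t = b/R, u = cos(gamma), D = sqrt(1 - 2 t u + t^2):

      V = (1 / 4 pi sigma R^2) * [ m_r (2 (u - t) / D^3 + (1/D - 1)/t)
          + m_t sin(gamma) (2 / D^3 + (D + 1) / (D (1 - t u + D))) ]
    """
    b = float(np.linalg.norm(src_pos))
    rhat = np.asarray(sensor, dtype=float) / R
    if b < 1e-14:
        return 3.0 * float(np.dot(moment, rhat)) / (4 * np.pi * sigma * R**2)
    r0hat = np.asarray(src_pos, dtype=float) / b
    u = float(np.clip(np.dot(rhat, r0hat), -1.0, 1.0))
    t = b / R
    D = np.sqrt(1.0 - 2.0 * t * u + t * t)
    m_r = float(np.dot(moment, r0hat))
    sin_g = np.sqrt(max(0.0, 1.0 - u * u))
    if sin_g > 1e-12:
        that = (rhat - u * r0hat) / sin_g
        m_t = float(np.dot(moment, that))
    else:
        m_t = 0.0
    radial = m_r * (2.0 * (u - t) / D**3 + (1.0 / D - 1.0) / t)
    tangential = m_t * sin_g * (2.0 / D**3
                                + (D + 1.0) / (D * (1.0 - t * u + D)))
    return (radial + tangential) / (4.0 * np.pi * sigma * R**2)


def ridge_source_estimate(L, C, weights, lam, y):
    """WMNE solution via the regularised normal equations.

    Solves (L^T C^-1 L + lam W^2) x = L^T C^-1 y with W = diag(weights),
    the direct (sensor-space-free) form of the weighted minimum-norm
    problem.
    """
    Cinv = np.linalg.inv(C)
    A = L.T @ Cinv @ L + lam * np.diag(np.asarray(weights, dtype=float) ** 2)
    return np.linalg.solve(A, L.T @ Cinv @ y)


def sign_aligned_mean(series):
    """Reference scout aggregation: explicit correlation-based sign flips."""
    x = np.asarray(series, dtype=float)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc = vt[0]
    signs = np.array([1.0 if float(row @ pc) >= 0 else -1.0 for row in x])
    if signs.sum() < 0 or (signs.sum() == 0 and signs[0] < 0):
        signs = -signs
    return np.mean([s * row for s, row in zip(signs, x)], axis=0)


def metrics_from_counts(conf):
    """Accuracy, kappa and macro precision/recall/F1 from first principles."""
    conf = np.asarray(conf, dtype=float)
    total = conf.sum()
    accuracy = np.trace(conf) / total
    row = conf.sum(axis=1)  # true-class counts
    col = conf.sum(axis=0)  # predicted counts
    p_o = accuracy
    p_e = float((row * col).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    present = row > 0
    precision = np.where(col > 0, np.diag(conf) / np.where(col > 0, col, 1), 0.0)
    recall = np.where(row > 0, np.diag(conf) / np.where(row > 0, row, 1), 0.0)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return {
        "accuracy": float(accuracy),
        "kappa": float(kappa),
        "precision": float(precision[present].mean()),
        "recall": float(recall[present].mean()),
        "f1": float(f1[present].mean()),
    }


def auc_trapezoid(y_true, scores):
    """One-vs-rest ROC area by explicit threshold sweep + trapezoid rule."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    P = y.sum()
    N = len(y) - P
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # process score ties together
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        tpr.append(tp / P)
        fpr.append(fp / N)
        i = j
    return float(np.trapezoid(tpr, fpr))
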