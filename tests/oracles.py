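"""Independent oracles used by the test suite.

Everything here is deliberately implemented via a different route than the
package code it checks: closed forms, hand arithmetic, tangent-space
integration, or third-party primitives.
"""

from __future__ import annotations

import numpy as np

CHI2_95_2 = 5.991464547107979  # chi2.ppf(0.95, 2)


def benettin_lorenz_lle(
    n_steps: int = 150000,
    dt: float = 0.01,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    burn: int = 20000,
) -> float:
    """Largest Lyapunov exponent of the Lorenz system by integrating the
    exact tangent-linear (variational) equations with periodic
    renormalisation — fully independent of any embedding/neighbour method."""

    def rhs(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    def jac(s):
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0],
                         [rho - z, -1.0, -x],
                         [y, x, -beta]])

    s = np.array([1.0, 1.0, 1.0])
    v = np.array([1.0, 0.0, 0.0])
    acc, cnt = 0.0, 0
    for i in range(n_steps):
        k1 = rhs(s);            l1 = jac(s) @ v
        k2 = rhs(s + dt / 2 * k1); l2 = jac(s + dt / 2 * k1) @ (v + dt / 2 * l1)
        k3 = rhs(s + dt / 2 * k2); l3 = jac(s + dt / 2 * k2) @ (v + dt / 2 * l2)
        k4 = rhs(s + dt * k3);     l4 = jac(s + dt * k3) @ (v + dt * l3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        v = v + dt / 6 * (l1 + 2 * l2 + 2 * l3 + l4)
        nv = np.linalg.norm(v)
        v /= nv
        if i >= burn:
            acc += np.log(nv)
            cnt += 1
    return acc / (cnt * dt)


def hand_mixed_anova(y: np.ndarray) -> dict:
    """Brute-force SS decomposition of a tiny balanced 2x2 mixed design.

    ``y`` has shape (2 groups, n_subjects, 2 conditions).  Returns the three
    F statistics computed from explicit cell/marginal means, the long way.
    """
    g, n, c = y.shape
    assert g == 2 and c == 2
    grand = y.mean()
    group_means = y.mean(axis=(1, 2))
    cond_means = y.mean(axis=(0, 1))
    cell_means = y.mean(axis=1)          # (group, cond)
    subj_means = y.mean(axis=2)          # (group, subject)

    ss_group = n * c * np.sum((group_means - grand) ** 2)
    ss_cond = g * n * np.sum((cond_means - grand) ** 2)
    ss_cell = n * np.sum((cell_means - grand) ** 2)
    ss_inter = ss_cell - ss_group - ss_cond
    ss_subj = c * np.sum((subj_means - group_means[:, None]) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cell - ss_subj

    df_subj = g * (n - 1)
    df_err = g * (n - 1)  # (conditions-1) x subjects-within-groups
    F_group = (ss_group / 1) / (ss_subj / df_subj)
    F_cond = (ss_cond / 1) / (ss_err / df_err)
    F_inter = (ss_inter / 1) / (ss_err / df_err)
    return {
        "F_group": F_group, "F_cond": F_cond, "F_inter": F_inter,
        "ss": {"group": ss_group, "cond": ss_cond, "inter": ss_inter,
               "subj": ss_subj, "err": ss_err, "total": ss_total},
        "df": (df_subj, df_err),
    }
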