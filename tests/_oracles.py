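"""Independent reference implementations used only by the tests.

Every function here evaluates the closed-form quantities with explicit
Python loops over cells, genes, components and latent dimensions — no shared
code with the package's vectorised implementation.
"""

from math import comb, log, sqrt

import numpy as np
from scipy.special import digamma


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def moments_loops(st):
    """Posterior expectations, one loop at a time."""
    N, L = st.z_mean.shape
    D = st.w_mean.shape[0]
    M = st.resp.shape[1]

    out = {}
    out["E_tau"] = st.tau_shape / st.tau_rate
    out["E_ln_tau"] = digamma(st.tau_shape) - log(st.tau_rate)
    out["E_alpha"] = np.array(
        [st.alpha_shape / st.alpha_rate[i] for i in range(L)]
    )
    out["E_ln_alpha"] = np.array(
        [digamma(st.alpha_shape) - log(st.alpha_rate[i]) for i in range(L)]
    )
    out["E_T"] = np.array(
        [st.T_dof[j] * np.linalg.inv(st.T_rate[j]) for j in range(M)]
    )
    out["E_ln_det_T"] = np.array(
        [
            sum(digamma((st.T_dof[j] + 1 - i) / 2) for i in range(1, L + 1))
            + L * log(2)
            - log(np.linalg.det(st.T_rate[j]))
            for j in range(M)
        ]
    )
    total = st.rho_conc.sum()
    out["E_ln_rho"] = np.array(
        [digamma(st.rho_conc[j]) - digamma(total) for j in range(M)]
    )
    out["E_zzT"] = np.array(
        [st.z_cov[n] + np.outer(st.z_mean[n], st.z_mean[n]) for n in range(N)]
    )
    wtw = np.zeros((L, L))
    for d in range(D):
        wtw += np.outer(st.w_mean[d], st.w_mean[d])
    out["E_WtW"] = wtw + D * st.w_cov
    out["E_col_norm2"] = np.array(
        [
            sum(st.w_mean[d, i] ** 2 for d in range(D)) + D * st.w_cov[i, i]
            for i in range(L)
        ]
    )
    out["E_mmT"] = np.array(
        [st.m_cov[j] + np.outer(st.m_mean[j], st.m_mean[j]) for j in range(M)]
    )
    out["E_mu_norm2"] = float(np.dot(st.mu_mean, st.mu_mean)) + D * st.mu_cov_scalar
    return out


# ---------------------------------------------------------------------------
# CAVI updates, exactly as printed, one cell / gene / component at a time
# ---------------------------------------------------------------------------

def latent_update_loops(st, X):
    mom = moments_loops(st)
    N, L = st.z_mean.shape
    M = st.resp.shape[1]
    covs, means = [], []
    for n in range(N):
        prec = mom["E_tau"] * mom["E_WtW"]
        for j in range(M):
            prec = prec + st.resp[n, j] * mom["E_T"][j]
        cov = np.linalg.inv(prec)
        rhs = (X[n] - st.mu_mean) @ (mom["E_tau"] * st.w_mean)
        for j in range(M):
            rhs = rhs + st.resp[n, j] * (st.m_mean[j] @ mom["E_T"][j])
        covs.append(cov)
        means.append(rhs @ cov)
    return np.array(means), np.array(covs)


def projection_update_loops(st, X):
    mom = moments_loops(st)
    N = st.z_mean.shape[0]
    D, L = st.w_mean.shape
    prec = np.diag(mom["E_alpha"])
    for n in range(N):
        prec = prec + mom["E_tau"] * mom["E_zzT"][n]
    cov = np.linalg.inv(prec)
    rows = []
    for d in range(D):
        acc = np.zeros(L)
        for n in range(N):
            acc = acc + st.z_mean[n] * (X[n, d] - st.mu_mean[d])
        rows.append(mom["E_tau"] * cov @ acc)
    return np.array(rows), cov


def offset_update_loops(st, X, beta):
    mom = moments_loops(st)
    N, D = X.shape
    scalar = 1.0 / (beta + N * mom["E_tau"])
    acc = np.zeros(D)
    for n in range(N):
        acc = acc + (X[n] - st.w_mean @ st.z_mean[n])
    return scalar * mom["E_tau"] * acc, scalar


def ard_update_loops(st, a_alpha, b_alpha):
    mom = moments_loops(st)
    D, L = st.w_mean.shape
    shape = a_alpha + D / 2
    rates = np.array([b_alpha + mom["E_col_norm2"][i] / 2 for i in range(L)])
    return shape, rates


def noise_update_loops(st, X, a_tau, b_tau):
    mom = moments_loops(st)
    N, D = X.shape
    shape = a_tau + N * D / 2
    acc = 0.0
    for n in range(N):
        x = X[n]
        pred = st.w_mean @ st.z_mean[n]
        acc += float(x @ x)
        acc += mom["E_mu_norm2"]
        acc += float(np.trace(mom["E_WtW"] @ mom["E_zzT"][n]))
        acc += 2.0 * float(st.mu_mean @ pred)
        acc -= 2.0 * float(x @ pred)
        acc -= 2.0 * float(x @ st.mu_mean)
    return shape, b_tau + acc / 2


def responsibilities_update_loops(st):
    mom = moments_loops(st)
    N = st.z_mean.shape[0]
    M = st.resp.shape[1]
    resp = np.zeros((N, M))
    for n in range(N):
        logs = []
        for j in range(M):
            S = (
                mom["E_zzT"][n]
                - np.outer(st.m_mean[j], st.z_mean[n])
                - np.outer(st.z_mean[n], st.m_mean[j])
                + mom["E_mmT"][j]
            )
            logs.append(
                mom["E_ln_det_T"][j] / 2
                + mom["E_ln_rho"][j]
                - float(np.trace(mom["E_T"][j] @ S)) / 2
            )
        logs = np.array(logs)
        p = np.exp(logs - logs.max())
        resp[n] = p / p.sum()
    return resp


def mixture_weights_update_loops(st, delta):
    M = st.resp.shape[1]
    return np.array([delta[j] + st.resp[:, j].sum() for j in range(M)])


def component_means_update_loops(st, gamma):
    mom = moments_loops(st)
    N, L = st.z_mean.shape
    M = st.resp.shape[1]
    covs, means = [], []
    for j in range(M):
        Nj = sum(st.resp[n, j] for n in range(N))
        cov = np.linalg.inv(gamma * np.eye(L) + Nj * mom["E_T"][j])
        acc = np.zeros(L)
        for n in range(N):
            acc = acc + st.resp[n, j] * st.z_mean[n]
        covs.append(cov)
        means.append(cov @ mom["E_T"][j] @ acc)
    return np.array(means), np.array(covs)


def component_precisions_update_loops(st, upsilon, V):
    mom = moments_loops(st)
    N, L = st.z_mean.shape
    M = st.resp.shape[1]
    dofs, rates = [], []
    for j in range(M):
        Nj = sum(st.resp[n, j] for n in range(N))
        dofs.append(upsilon + Nj)
        acc = V.copy()
        for n in range(N):
            s = st.resp[n, j]
            acc = acc + s * mom["E_zzT"][n]
            acc = acc - s * np.outer(st.z_mean[n], st.m_mean[j])
            acc = acc - s * np.outer(st.m_mean[j], st.z_mean[n])
            acc = acc + s * mom["E_mmT"][j]
        rates.append((acc + acc.T) / 2)
    return np.array(dofs), np.array(rates)


# ---------------------------------------------------------------------------
# clustering metric oracles, straight from the formulas
# ---------------------------------------------------------------------------

def ari_loops(pred, truth):
    pred = list(pred)
    truth = list(truth)
    n = len(pred)
    clusters = sorted(set(pred), key=str)
    types = sorted(set(truth), key=str)
    table = [
        [sum(1 for p, t in zip(pred, truth) if p == c and t == ty) for ty in types]
        for c in clusters
    ]
    sum_ij = sum(comb(v, 2) for row in table for v in row)
    sum_x = sum(comb(sum(row), 2) for row in table)
    sum_y = sum(comb(sum(table[i][j] for i in range(len(clusters))), 2)
                for j in range(len(types)))
    pairs = comb(n, 2)
    expected = sum_x * sum_y / pairs
    maximum = (sum_x + sum_y) / 2
    if maximum == expected:
        same = all(
            sum(1 for v in row if v > 0) == 1 for row in table
        ) and all(
            sum(1 for i in range(len(clusters)) if table[i][j] > 0) == 1
            for j in range(len(types))
        )
        return 1.0 if same else 0.0
    return (sum_ij - expected) / (maximum - expected)


def nmi_loops(pred, truth):
    pred = list(pred)
    truth = list(truth)
    n = len(pred)
    clusters = sorted(set(pred), key=str)
    types = sorted(set(truth), key=str)
    h_c = 0.0
    for c in clusters:
        p = sum(1 for v in pred if v == c) / n
        h_c -= p * log(p)
    h_t = 0.0
    for ty in types:
        p = sum(1 for v in truth if v == ty) / n
        h_t -= p * log(p)
    mi = 0.0
    for c in clusters:
        for ty in types:
            joint = sum(1 for p, t in zip(pred, truth) if p == c and t == ty) / n
            if joint > 0:
                pc = sum(1 for v in pred if v == c) / n
                pt = sum(1 for v in truth if v == ty) / n
                mi += joint * log(joint / (pc * pt))
    if h_c == 0.0 or h_t == 0.0:
        return 0.0
    return mi / sqrt(h_c * h_t)


def all_partitions(n):
    """All set partitions of range(n), as label vectors."""
    if n == 0:
        yield []
        return
    for rest in all_partitions(n - 1):
        k = max(rest) + 1 if rest else 0
        for label in range(k + 1):
            yield rest + [label]
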