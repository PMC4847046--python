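"""Independent brute-force oracles used to verify the package.

Everything here is deliberately written from first principles with plain
Python loops and its own trigonometry — no imports from the package's
numerical code paths — so agreement is meaningful.
"""

import math

import numpy as np


def oracle_gamma(model_type, nugget, psill, range_major, range_minor, azimuth_deg,
                 dx, dy):
    """Model semivariance for one lag vector, recomputed independently."""
    h = math.hypot(dx, dy)
    if h == 0.0:
        return 0.0
    t = math.radians(azimuth_deg)
    h_maj = dx * math.sin(t) + dy * math.cos(t)
    h_min = dx * math.cos(t) - dy * math.sin(t)
    he = math.sqrt((h_maj / range_major) ** 2 + (h_min / range_minor) ** 2)
    if model_type == "gaussian":
        g = 1.0 - math.exp(-3.0 * he * he)
    elif model_type == "exponential":
        g = 1.0 - math.exp(-3.0 * he)
    elif model_type == "spherical":
        u = min(he, 1.0)
        g = 1.5 * u - 0.5 * u ** 3
    else:
        raise ValueError(model_type)
    return nugget + psill * g


def gamma_of(model, dx, dy, sign=1.0):
    """Oracle gamma evaluated from a package VariogramModel's parameters."""
    return sign * oracle_gamma(
        model.model_type, model.nugget, model.partial_sill,
        model.range_major, model.range_minor, model.azimuth_major, dx, dy,
    )


def brute_force_variogram(coords, values, lag_width, n_lags,
                          direction=None, angle_tol=22.5):
    """All-pairs O(N^2) accumulation of the binned semivariance."""
    n = len(coords)
    sums = [0.0] * n_lags
    counts = [0] * n_lags
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[j][0] - coords[i][0]
            dy = coords[j][1] - coords[i][1]
            d = math.hypot(dx, dy)
            if d == 0.0:
                continue
            if direction is not None:
                az = math.degrees(math.atan2(dx, dy)) % 180.0
                diff = abs(az - direction % 180.0)
                diff = min(diff, 180.0 - diff)
                if diff > angle_tol + 1e-12:
                    continue
            k = int(d // lag_width)
            if k >= n_lags:
                continue
            sums[k] += (values[i] - values[j]) ** 2
            counts[k] += 1
    lags, gam, cnt = [], [], []
    for k in range(n_lags):
        if counts[k] > 0:
            lags.append((k + 0.5) * lag_width)
            gam.append(sums[k] / (2.0 * counts[k]))
            cnt.append(counts[k])
    return np.array(lags), np.array(gam), np.array(cnt)


def brute_force_cross_variogram(coords, z1, z2, lag_width, n_lags):
    """All-pairs cross-semivariance over co-located observations."""
    n = len(coords)
    sums = [0.0] * n_lags
    counts = [0] * n_lags
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[j][0] - coords[i][0]
            dy = coords[j][1] - coords[i][1]
            d = math.hypot(dx, dy)
            if d == 0.0:
                continue
            k = int(d // lag_width)
            if k >= n_lags:
                continue
            sums[k] += (z1[i] - z1[j]) * (z2[i] - z2[j])
            counts[k] += 1
    lags, gam, cnt = [], [], []
    for k in range(n_lags):
        if counts[k] > 0:
            lags.append((k + 0.5) * lag_width)
            gam.append(sums[k] / (2.0 * counts[k]))
            cnt.append(counts[k])
    return np.array(lags), np.array(gam), np.array(cnt)


def ok_oracle(coords, values, model, target):
    """Dense ordinary-kriging solve assembled entry by entry."""
    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma_of(model, coords[j][0] - coords[i][0],
                               coords[j][1] - coords[i][1])
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma_of(model, target[0] - coords[i][0], target[1] - coords[i][1])
    b[n] = 1.0
    x = np.linalg.solve(A, b)
    lam, mu = x[:n], x[n]
    est = float(lam @ np.asarray(values))
    var = float(lam @ b[:n] + mu)
    return lam, mu, est, var


def ck_oracle(pc, pv, sc, sv, lmc, target, cross_sign=1.0):
    """Dense ordinary co-kriging solve with two unbiasedness constraints."""
    n, m = len(pc), len(sc)
    sz = n + m + 2
    A = np.zeros((sz, sz))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma_of(lmc.direct_primary,
                               pc[j][0] - pc[i][0], pc[j][1] - pc[i][1])
        for j in range(m):
            A[i, n + j] = gamma_of(lmc.cross, sc[j][0] - pc[i][0],
                                   sc[j][1] - pc[i][1], cross_sign)
            A[n + j, i] = A[i, n + j]
        A[i, n + m] = 1.0
        A[n + m, i] = 1.0
    for i in range(m):
        for j in range(m):
            A[n + i, n + j] = gamma_of(lmc.direct_secondary,
                                       sc[j][0] - sc[i][0], sc[j][1] - sc[i][1])
        A[n + i, n + m + 1] = 1.0
        A[n + m + 1, n + i] = 1.0
    b = np.zeros(sz)
    for i in range(n):
        b[i] = gamma_of(lmc.direct_primary, target[0] - pc[i][0],
                        target[1] - pc[i][1])
    for j in range(m):
        b[n + j] = gamma_of(lmc.cross, target[0] - sc[j][0],
                            target[1] - sc[j][1], cross_sign)
    b[n + m] = 1.0
    x = np.linalg.solve(A, b)
    lam, k = x[:n], x[n:n + m]
    est = float(lam @ np.asarray(pv) + k @ np.asarray(sv))
    var = float(lam @ b[:n] + k @ b[n:n + m] + x[n + m])
    return lam, k, est, var
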