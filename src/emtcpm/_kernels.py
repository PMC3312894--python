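"""Numba kernels for the Metropolis index-copy engine.

All stochastic choices consume a single xorshift64* stream whose 64-bit state
is threaded through every kernel as a one-element uint64 array, so a run is a
pure function of the initial seed.
"""

import numpy as np
from numba import njit

_XSMULT = np.uint64(0x2545F4914F6CDD1D)
_INV53 = 1.0 / float(1 << 53)


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    return (x * _XSMULT) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def rng_uniform(state):
    """Uniform double in [0, 1)."""
    return float(_rng_next(state) >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def rng_below(state, n):
    """Uniform integer in [0, n)."""
    return int(rng_uniform(state) * n)


@njit(cache=True)
def run_mcs_kernel(
    spin,            # (nx,ny,nz) int32, 0 = medium
    ctype,           # (ncap,) int32 type index per cell id (0 = medium type)
    volume,          # (ncap,) int64
    surface,         # (ncap,) int64
    tvol,            # (ncap,) float64 target volumes
    tsurf,           # (ncap,) float64 target surfaces
    cx, cy, cz,      # (ncap,) float64 centroid coordinate sums
    alive,           # (ncap,) uint8
    jtable,          # (ntype,ntype) float64 boundary-energy coefficients
    lam_v,           # (ntype,) float64, 0 for medium
    lam_s,           # (ntype,) float64, 0 for medium
    mu,              # (ntype,) float64 chemotaxis coefficient per type
    chemo,           # (nx,ny,nz) float64 concentration field
    use_chemo,       # bool
    offsets,         # (noff,3) int64 copy/contact neighbourhood
    temperature,     # float64
    state,           # (1,) uint64 rng state
    n_attempts,      # int64
):
    """Run ``n_attempts`` pixel-copy attempts; return bookkeeping.

    Returns (attempts, acceptances, net_dH, net_dH_chemo,
             last_dH, last_accepted, last_kind, last_tx..sz)
    where last_kind is 0 = proposal evaluated, 1 = same-index no-op,
    2 = source off-lattice.
    """
    nx, ny, nz = spin.shape
    noff = offsets.shape[0]
    acc = 0
    net_dh = 0.0
    net_dh_chemo = 0.0
    last_dh = 0.0
    last_acc = 0
    last_kind = 2
    ltx = lty = ltz = lsx = lsy = lsz = -1

    for _ in range(n_attempts):
        tx = rng_below(state, nx)
        ty = rng_below(state, ny)
        tz = rng_below(state, nz)
        k = rng_below(state, noff)
        sx = tx + offsets[k, 0]
        sy = ty + offsets[k, 1]
        sz = tz + offsets[k, 2]
        last_acc = 0
        ltx, lty, ltz, lsx, lsy, lsz = tx, ty, tz, sx, sy, sz
        if sx < 0 or sx >= nx or sy < 0 or sy >= ny or sz < 0 or sz >= nz:
            last_kind = 2
            last_dh = 0.0
            continue
        a = spin[tx, ty, tz]          # index being overwritten
        b = spin[sx, sy, sz]          # source index copied onto the target
        if a == b:
            last_kind = 1
            last_dh = 0.0
            continue
        last_kind = 0
        ta = ctype[a]
        tb = ctype[b]

        # --- boundary (adhesion) term over the copy neighbourhood
        dh = 0.0
        for m in range(noff):
            jx = tx + offsets[m, 0]
            jy = ty + offsets[m, 1]
            jz = tz + offsets[m, 2]
            if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                continue
            sj = spin[jx, jy, jz]
            tj = ctype[sj]
            if sj != b:
                dh += jtable[tb, tj]
            if sj != a:
                dh -= jtable[ta, tj]

        # --- volume constraint (medium exempt via lam_v[0] = 0)
        if a != 0:
            va = float(volume[a])
            dh += lam_v[ta] * ((va - 1.0 - tvol[a]) ** 2 - (va - tvol[a]) ** 2)
        if b != 0:
            vb = float(volume[b])
            dh += lam_v[tb] * ((vb + 1.0 - tvol[b]) ** 2 - (vb - tvol[b]) ** 2)

        # --- surface constraint: first-neighbour boundary links around t
        n_in_a = 0
        n_in_b = 0
        n_tot = 0
        for axis in range(3):
            for sgn in range(-1, 2, 2):
                jx, jy, jz = tx, ty, tz
                if axis == 0:
                    jx += sgn
                elif axis == 1:
                    jy += sgn
                else:
                    jz += sgn
                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    continue
                n_tot += 1
                sj = spin[jx, jy, jz]
                if sj == a:
                    n_in_a += 1
                elif sj == b:
                    n_in_b += 1
        ds_a = 2 * n_in_a - n_tot
        ds_b = n_tot - 2 * n_in_b
        if a != 0:
            sa = float(surface[a])
            dh += lam_s[ta] * ((sa + ds_a - tsurf[a]) ** 2 - (sa - tsurf[a]) ** 2)
        if b != 0:
            sb = float(surface[b])
            dh += lam_s[tb] * ((sb + ds_b - tsurf[b]) ** 2 - (sb - tsurf[b]) ** 2)

        # --- chemotaxis bias (quasi energy, positive mu climbs the gradient)
        dh_chem = 0.0
        if use_chemo:
            dc = chemo[tx, ty, tz] - chemo[sx, sy, sz]
            dh_chem = -(mu[tb] - mu[ta]) * dc
            dh += dh_chem

        last_dh = dh
        if dh <= 0.0:
            accept = True
        else:
            accept = rng_uniform(state) < np.exp(-dh / temperature)
        if accept:
            spin[tx, ty, tz] = b
            volume[a] -= 1
            volume[b] += 1
            if a != 0:       # the medium carries no surface bookkeeping
                surface[a] += ds_a
            if b != 0:
                surface[b] += ds_b
            cx[a] -= tx
            cy[a] -= ty
            cz[a] -= tz
            cx[b] += tx
            cy[b] += ty
            cz[b] += tz
            if a != 0 and volume[a] == 0:
                alive[a] = 0
                surface[a] = 0
            acc += 1
            net_dh += dh
            net_dh_chemo += dh_chem
            last_acc = 1

    return (n_attempts, acc, net_dh, net_dh_chemo,
            last_dh, last_acc, last_kind, ltx, lty, ltz, lsx, lsy, lsz)


@njit(cache=True)
def contact_counts_kernel(spin, ncap):
    """First-neighbour boundary links per cell id.

    Returns (boundary, contact): ``boundary[i]`` counts links from cell i to
    any other index (the surface measure), ``contact[i]`` only links to other
    non-medium cells (the numerator of the contact fraction g).
    """
    nx, ny, nz = spin.shape
    boundary = np.zeros(ncap, dtype=np.int64)
    contact = np.zeros(ncap, dtype=np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                p = spin[x, y, z]
                for axis in range(3):
                    jx, jy, jz = x, y, z
                    if axis == 0:
                        jx += 1
                    elif axis == 1:
                        jy += 1
                    else:
                        jz += 1
                    if jx >= nx or jy >= ny or jz >= nz:
                        continue
                    q = spin[jx, jy, jz]
                    if p == q:
                        continue
                    boundary[p] += 1
                    boundary[q] += 1
                    if p != 0 and q != 0:
                        contact[p] += 1
                        contact[q] += 1
    return boundary, contact


@njit(cache=True)
def metropolis_trials_kernel(delta_h, temperature, n_trials, state):
    """Count acceptances of ``n_trials`` Metropolis decisions at fixed dH."""
    acc = 0
    if delta_h <= 0.0:
        p = 1.0
    else:
        p = np.exp(-delta_h / temperature)
    for _ in range(n_trials):
        if rng_uniform(state) < p:
            acc += 1
    return acc
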