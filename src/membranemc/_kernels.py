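"""Numba-compiled hot loops for pair energies, totals, and move deltas.

Every function works on flat float64 arrays and scalar parameters so the
compiled signatures stay simple.  Charge bookkeeping: with C0 =
energy_unit_scale * dipole_charge**2, the Coulomb prefactors are C0 for
dipole-dipole, C0*q for dipole-dopant, and C0*q1*q2 for dopant-dopant pairs
(dopant charges are multiples of the dipole pole charge).

All pair terms are gated on the *center* separation by an optional cutoff
radius (``rcut2`` = squared cutoff; pass a huge value to disable): a pair
farther apart than the cutoff contributes exactly zero.  The same rule is
applied everywhere (pair API, totals, incremental deltas), so incremental and
full summation remain consistent to rounding error.

Periodic mode applies the minimum-image convention to center separations
before the charge offsets are added, which is exact while dipole length <<
box.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: squared-cutoff sentinel that disables the cutoff
NO_CUTOFF2 = 1e300


@njit(cache=False, fastmath=False)
def _min_image(d: float, box: float) -> float:
    return d - box * math.floor(d / box + 0.5)


@njit(cache=False, fastmath=False)
def _lj(r2: float, four_eps: float, sigma: float) -> float:
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return four_eps * (s6 * s6 - s6)


@njit(cache=False, fastmath=False)
def dd_pair(
    dx: float,
    dy: float,
    ai: float,
    aj: float,
    a: float,
    c0: float,
    four_eps: float,
    sigma: float,
    rcut2: float,
) -> tuple:
    """Coulomb and LJ energy of two finite dipoles separated by (dx, dy).

    Each dipole carries +e at center + a*(cos alpha, sin alpha) and -e at the
    mirrored point; the Coulomb part is the signed sum over the four
    charge-charge terms, the LJ part acts on the center separation.
    """
    r2 = dx * dx + dy * dy
    if r2 > rcut2:
        return 0.0, 0.0
    uxi = a * math.cos(ai)
    uyi = a * math.sin(ai)
    uxj = a * math.cos(aj)
    uyj = a * math.sin(aj)
    # (+i,+j)
    ex = dx + uxj - uxi
    ey = dy + uyj - uyi
    coul = 1.0 / math.sqrt(ex * ex + ey * ey)
    # (+i,-j)
    ex = dx - uxj - uxi
    ey = dy - uyj - uyi
    coul -= 1.0 / math.sqrt(ex * ex + ey * ey)
    # (-i,+j)
    ex = dx + uxj + uxi
    ey = dy + uyj + uyi
    coul -= 1.0 / math.sqrt(ex * ex + ey * ey)
    # (-i,-j)
    ex = dx - uxj + uxi
    ey = dy - uyj + uyi
    coul += 1.0 / math.sqrt(ex * ex + ey * ey)
    return c0 * coul, _lj(r2, four_eps, sigma)


@njit(cache=False, fastmath=False)
def dp_pair(
    dx: float,
    dy: float,
    ai: float,
    a: float,
    c0q: float,
    four_eps: float,
    sigma_dp: float,
    rcut2: float,
) -> tuple:
    """Coulomb and LJ energy of a dipole and a dopant separated by (dx, dy)."""
    r2 = dx * dx + dy * dy
    if r2 > rcut2:
        return 0.0, 0.0
    ux = a * math.cos(ai)
    uy = a * math.sin(ai)
    ex = dx - ux
    ey = dy - uy
    coul = 1.0 / math.sqrt(ex * ex + ey * ey)
    ex = dx + ux
    ey = dy + uy
    coul -= 1.0 / math.sqrt(ex * ex + ey * ey)
    return c0q * coul, _lj(r2, four_eps, sigma_dp)


@njit(cache=False, fastmath=False)
def pp_pair(
    dx: float, dy: float, c0qq: float, four_eps: float, contact_L: float, rcut2: float
) -> tuple:
    """Coulomb and LJ energy of two dopants separated by (dx, dy)."""
    r2 = dx * dx + dy * dy
    if r2 > rcut2:
        return 0.0, 0.0
    return c0qq / math.sqrt(r2), _lj(r2, four_eps, contact_L)


@njit(cache=False, fastmath=False)
def total_energy(
    dip_pos: np.ndarray,
    dip_alpha: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    dop_L: np.ndarray,
    a: float,
    c0: float,
    four_eps: float,
    sigma: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> tuple:
    """(coulomb, lj) totals over all unordered particle pairs, in a.u."""
    nd = dip_pos.shape[0]
    npp = dop_pos.shape[0]
    coul = 0.0
    lj = 0.0
    for i in range(nd):
        xi = dip_pos[i, 0]
        yi = dip_pos[i, 1]
        ai = dip_alpha[i]
        for j in range(i + 1, nd):
            dx = dip_pos[j, 0] - xi
            dy = dip_pos[j, 1] - yi
            if periodic:
                dx = _min_image(dx, bw)
                dy = _min_image(dy, bh)
            c, l = dd_pair(dx, dy, ai, dip_alpha[j], a, c0, four_eps, sigma, rcut2)
            coul += c
            lj += l
        for m in range(npp):
            dx = dop_pos[m, 0] - xi
            dy = dop_pos[m, 1] - yi
            if periodic:
                dx = _min_image(dx, bw)
                dy = _min_image(dy, bh)
            c, l = dp_pair(dx, dy, ai, a, c0 * dop_q[m], four_eps, sigma_dp, rcut2)
            coul += c
            lj += l
    for m in range(npp):
        for n in range(m + 1, npp):
            dx = dop_pos[n, 0] - dop_pos[m, 0]
            dy = dop_pos[n, 1] - dop_pos[m, 1]
            if periodic:
                dx = _min_image(dx, bw)
                dy = _min_image(dy, bh)
            cl = 0.5 * (dop_L[m] + dop_L[n])
            c, l = pp_pair(dx, dy, c0 * dop_q[m] * dop_q[n], four_eps, cl, rcut2)
            coul += c
            lj += l
    return coul, lj


@njit(cache=False, fastmath=False)
def _dipole_site_energy(
    i: int,
    x: float,
    y: float,
    alpha: float,
    dip_pos: np.ndarray,
    dip_alpha: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    a: float,
    c0: float,
    four_eps: float,
    sigma: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    """Total interaction of a (virtual) dipole at (x, y, alpha) with everyone
    except dipole ``i`` (pass i < 0 to include all dipoles)."""
    e = 0.0
    for j in range(dip_pos.shape[0]):
        if j == i:
            continue
        dx = dip_pos[j, 0] - x
        dy = dip_pos[j, 1] - y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        c, l = dd_pair(dx, dy, alpha, dip_alpha[j], a, c0, four_eps, sigma, rcut2)
        e += c + l
    for m in range(dop_pos.shape[0]):
        dx = dop_pos[m, 0] - x
        dy = dop_pos[m, 1] - y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        c, l = dp_pair(dx, dy, alpha, a, c0 * dop_q[m], four_eps, sigma_dp, rcut2)
        e += c + l
    return e


@njit(cache=False, fastmath=False)
def delta_dipole_move(
    i: int,
    new_x: float,
    new_y: float,
    new_alpha: float,
    dip_pos: np.ndarray,
    dip_alpha: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    a: float,
    c0: float,
    four_eps: float,
    sigma: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    """Energy change of moving dipole i to (new_x, new_y, new_alpha), a.u."""
    old = _dipole_site_energy(
        i, dip_pos[i, 0], dip_pos[i, 1], dip_alpha[i],
        dip_pos, dip_alpha, dop_pos, dop_q,
        a, c0, four_eps, sigma, sigma_dp, periodic, bw, bh, rcut2,
    )
    new = _dipole_site_energy(
        i, new_x, new_y, new_alpha,
        dip_pos, dip_alpha, dop_pos, dop_q,
        a, c0, four_eps, sigma, sigma_dp, periodic, bw, bh, rcut2,
    )
    return new - old


@njit(cache=False, fastmath=False)
def _dopant_site_energy(
    m: int,
    x: float,
    y: float,
    dip_pos: np.ndarray,
    dip_alpha: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    dop_L: np.ndarray,
    a: float,
    c0: float,
    four_eps: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    q_m = dop_q[m]
    L_m = dop_L[m]
    e = 0.0
    for j in range(dip_pos.shape[0]):
        dx = x - dip_pos[j, 0]
        dy = y - dip_pos[j, 1]
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        c, l = dp_pair(dx, dy, dip_alpha[j], a, c0 * q_m, four_eps, sigma_dp, rcut2)
        e += c + l
    for n in range(dop_pos.shape[0]):
        if n == m:
            continue
        dx = dop_pos[n, 0] - x
        dy = dop_pos[n, 1] - y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        cl = 0.5 * (L_m + dop_L[n])
        c, l = pp_pair(dx, dy, c0 * q_m * dop_q[n], four_eps, cl, rcut2)
        e += c + l
    return e


@njit(cache=False, fastmath=False)
def delta_dopant_move(
    m: int,
    new_x: float,
    new_y: float,
    dip_pos: np.ndarray,
    dip_alpha: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    dop_L: np.ndarray,
    a: float,
    c0: float,
    four_eps: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    """Energy change of moving dopant m to (new_x, new_y), a.u."""
    old = _dopant_site_energy(
        m, dop_pos[m, 0], dop_pos[m, 1],
        dip_pos, dip_alpha, dop_pos, dop_q, dop_L,
        a, c0, four_eps, sigma_dp, periodic, bw, bh, rcut2,
    )
    new = _dopant_site_energy(
        m, new_x, new_y,
        dip_pos, dip_alpha, dop_pos, dop_q, dop_L,
        a, c0, four_eps, sigma_dp, periodic, bw, bh, rcut2,
    )
    return new - old


# ----------------------------------------------------------------------
# Fused old/new kernels used by the chain driver.  Charge offsets
# a*(cos alpha, sin alpha) are cached in dip_ux/dip_uy so the inner loop does
# no trigonometry; fastmath lets LLVM pipeline the reciprocal square roots.
# ----------------------------------------------------------------------


@njit(cache=False, fastmath=True)
def delta_dipole_move_cached(
    i: int,
    new_x: float,
    new_y: float,
    new_ux: float,
    new_uy: float,
    dip_pos: np.ndarray,
    dip_ux: np.ndarray,
    dip_uy: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    c0: float,
    four_eps: float,
    sigma: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    """Fused old/new move delta for dipole i using cached charge offsets."""
    ox = dip_pos[i, 0]
    oy = dip_pos[i, 1]
    oux = dip_ux[i]
    ouy = dip_uy[i]
    dE = 0.0
    for j in range(dip_pos.shape[0]):
        if j == i:
            continue
        xj = dip_pos[j, 0]
        yj = dip_pos[j, 1]
        uxj = dip_ux[j]
        uyj = dip_uy[j]
        # --- old configuration ---
        dx = xj - ox
        dy = yj - oy
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx + uxj - oux
            ey = dy + uyj - ouy
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx - uxj - oux
            ey = dy - uyj - ouy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + uxj + oux
            ey = dy + uyj + ouy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx - uxj + oux
            ey = dy - uyj + ouy
            c += 1.0 / math.sqrt(ex * ex + ey * ey)
            dE -= c0 * c + _lj(r2, four_eps, sigma)
        # --- new configuration ---
        dx = xj - new_x
        dy = yj - new_y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx + uxj - new_ux
            ey = dy + uyj - new_uy
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx - uxj - new_ux
            ey = dy - uyj - new_uy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + uxj + new_ux
            ey = dy + uyj + new_uy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx - uxj + new_ux
            ey = dy - uyj + new_uy
            c += 1.0 / math.sqrt(ex * ex + ey * ey)
            dE += c0 * c + _lj(r2, four_eps, sigma)
    for mm in range(dop_pos.shape[0]):
        xj = dop_pos[mm, 0]
        yj = dop_pos[mm, 1]
        cq = c0 * dop_q[mm]
        dx = xj - ox
        dy = yj - oy
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx - oux
            ey = dy - ouy
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + oux
            ey = dy + ouy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            dE -= cq * c + _lj(r2, four_eps, sigma_dp)
        dx = xj - new_x
        dy = yj - new_y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx - new_ux
            ey = dy - new_uy
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + new_ux
            ey = dy + new_uy
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            dE += cq * c + _lj(r2, four_eps, sigma_dp)
    return dE


@njit(cache=False, fastmath=True)
def delta_dopant_move_cached(
    m: int,
    new_x: float,
    new_y: float,
    dip_pos: np.ndarray,
    dip_ux: np.ndarray,
    dip_uy: np.ndarray,
    dop_pos: np.ndarray,
    dop_q: np.ndarray,
    dop_L: np.ndarray,
    c0: float,
    four_eps: float,
    sigma_dp: float,
    periodic: bool,
    bw: float,
    bh: float,
    rcut2: float,
) -> float:
    """Fused old/new move delta for dopant m using cached charge offsets."""
    ox = dop_pos[m, 0]
    oy = dop_pos[m, 1]
    q_m = dop_q[m]
    L_m = dop_L[m]
    cq = c0 * q_m
    dE = 0.0
    for j in range(dip_pos.shape[0]):
        xj = dip_pos[j, 0]
        yj = dip_pos[j, 1]
        uxj = dip_ux[j]
        uyj = dip_uy[j]
        dx = ox - xj
        dy = oy - yj
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx - uxj
            ey = dy - uyj
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + uxj
            ey = dy + uyj
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            dE -= cq * c + _lj(r2, four_eps, sigma_dp)
        dx = new_x - xj
        dy = new_y - yj
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            ex = dx - uxj
            ey = dy - uyj
            c = 1.0 / math.sqrt(ex * ex + ey * ey)
            ex = dx + uxj
            ey = dy + uyj
            c -= 1.0 / math.sqrt(ex * ex + ey * ey)
            dE += cq * c + _lj(r2, four_eps, sigma_dp)
    for n in range(dop_pos.shape[0]):
        if n == m:
            continue
        cl = 0.5 * (L_m + dop_L[n])
        cqq = cq * dop_q[n]
        dx = dop_pos[n, 0] - ox
        dy = dop_pos[n, 1] - oy
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            dE -= cqq / math.sqrt(r2) + _lj(r2, four_eps, cl)
        dx = dop_pos[n, 0] - new_x
        dy = dop_pos[n, 1] - new_y
        if periodic:
            dx = _min_image(dx, bw)
            dy = _min_image(dy, bh)
        r2 = dx * dx + dy * dy
        if r2 <= rcut2:
            dE += cqq / math.sqrt(r2) + _lj(r2, four_eps, cl)
    return dE
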