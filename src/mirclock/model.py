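"""Core dynamics of the miR-206-mediated mammalian circadian clock.

The model tracks 19 concentrations (nM) coupled by Hill-type
transcription terms, Michaelis–Menten (de)phosphorylation/degradation
and mass-action transport/complex-formation kinetics:

* a BMAL1 arm — Bmal1 mRNA ``M_B`` and the cytosolic/nuclear,
  un-/phosphorylated BMAL1 proteins ``B_c``, ``B_cp``, ``B_n``,
  ``B_np`` — whose transcription is repressed by the nuclear
  BMAL1–CLOCK complex ``I_N`` (the main negative feedback loop);
* a CLOCK arm — Clock mRNA ``M_P`` and the CLOCK phosphoforms ``P0``,
  ``P1``, ``P2`` plus nuclear CLOCK ``P_N`` — with Clock transcription
  repressed by ``P_N`` (second negative loop); ``B_n`` and ``P_N``
  associate into ``I_N``;
* a MYOD1/miR-206 arm — Myod1 mRNA ``M_my`` (activated by ``I_N``),
  cytosolic MYOD1 ``MY_C``/``MY_cp``, the muscle-specific microRNA
  ``miR`` (driven by MYOD1), and the miR-206·Clock-mRNA silencing
  complex ``R_ISC`` whose formation (rate ``C3·miR·M_P``) removes
  Clock mRNA — the post-transcriptional coupling this model studies;
* three gene bookkeeping variables ``G_B``, ``G_C``, ``G_M`` that
  receive input from ``I_N``/``P_N`` but feed back into nothing.

All time units are hours, all concentrations nM.  The system is
autonomous; ``t`` is accepted for solver compatibility only.

Every kinetic term of the 19 rate equations is registered exactly once
as one of 49 named reaction fluxes (terms shared between equations,
e.g. a transcription Hill term that appears as a sink for a gene
variable and a source for its mRNA, count once).  The signed incidence
of fluxes on species (``STOICHIOMETRY``) reproduces the hand-written
right-hand side to floating-point round-off, which the test-suite
checks as a bookkeeping contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "FLUXES",
    "FLUX_IDS",
    "N_FLUXES",
    "STOICHIOMETRY",
    "FluxInfo",
    "species_index",
    "make_rhs",
    "rhs",
    "make_flux_evaluator",
    "fluxes",
    "flux_table",
    "rhs_from_fluxes",
]

#: the 19 dynamic species, in equation order of the model definition
SPECIES: tuple[str, ...] = (
    "G_B",    # Bmal1 gene variable
    "G_C",    # Clock gene variable
    "G_M",    # Myod1 gene variable
    "M_B",    # Bmal1 mRNA
    "M_my",   # Myod1 mRNA
    "M_P",    # Clock mRNA
    "MY_C",   # cytosolic MYOD1
    "MY_cp",  # cytosolic phosphorylated MYOD1
    "B_c",    # cytosolic BMAL1
    "B_cp",   # cytosolic phosphorylated BMAL1
    "B_n",    # nuclear BMAL1
    "B_np",   # nuclear phosphorylated BMAL1
    "P0",     # cytosolic CLOCK, unphosphorylated
    "P1",     # cytosolic CLOCK, singly phosphorylated
    "P2",     # cytosolic CLOCK, doubly phosphorylated
    "P_N",    # nuclear CLOCK
    "I_N",    # nuclear BMAL1-CLOCK complex
    "miR",    # miR-206
    "R_ISC",  # miR-206 . Clock-mRNA silencing complex
)

N_SPECIES = len(SPECIES)

_IDX = {name: i for i, name in enumerate(SPECIES)}


def species_index(name: str) -> int:
    """Index of a species in the state vector; raises on unknown names."""
    try:
        return _IDX[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; valid names: {SPECIES}") from None


@dataclass(frozen=True)
class FluxInfo:
    """One reaction flux: a single kinetic term of the rate equations."""

    id: str            # canonical identifier R1..R49
    name: str          # human-readable reaction name
    params: tuple[str, ...]   # rate constants appearing in the rate law
    species: tuple[str, ...]  # state variables appearing in the rate law
    equations: tuple[int, ...]  # 1-based rate-equation numbers the term occurs in


# ---------------------------------------------------------------------------
# Flux registry.  R1-R24 and R37-R45: BMAL1/MYOD1 arm and the complex /
# miR-206 reactions, named as in the field's convention for this network.
# R25-R36: the CLOCK arm, in equation order.  R46-R49: the constitutive
# production and first-order decay of the Bmal1/Myod1 gene variables.
# ---------------------------------------------------------------------------
FLUXES: tuple[FluxInfo, ...] = (
    FluxInfo("R1", "Bmal1 mRNA formation", ("V_sB", "K_IB", "m1"), ("I_N",), (1, 4)),
    FluxInfo("R2", "Bmal1 mRNA degradation", ("V_mB", "K_mB"), ("M_B",), (4,)),
    FluxInfo("R3", "cytosolic BMAL1 formation", ("k_sB",), ("M_B",), (10,)),
    FluxInfo("R4", "cytosolic BMAL1 phosphorylation", ("V_1B", "K_p1"), ("B_c",), (10, 11)),
    FluxInfo("R5", "cytosolic BMAL1 dephosphorylation", ("V_2B", "K_dp1"), ("B_cp",), (10, 11)),
    FluxInfo("R6", "cytosolic BMAL1 nonspecific degradation", ("k_dn1",), ("B_c",), (10,)),
    FluxInfo("R7", "cytosolic phosphorylated BMAL1 degradation", ("V_dBC", "K_d1"), ("B_cp",), (11,)),
    FluxInfo("R8", "cytosolic phosphorylated BMAL1 nonspecific degradation", ("k_dn2",), ("B_cp",), (11,)),
    FluxInfo("R9", "BMAL1 entry into the nucleus", ("k1",), ("B_c",), (9, 10)),
    FluxInfo("R10", "BMAL1 exit from the nucleus", ("k2",), ("B_n",), (9, 10)),
    FluxInfo("R11", "nuclear BMAL1 nonspecific degradation", ("k_dn3",), ("B_n",), (9,)),
    FluxInfo("R12", "nuclear BMAL1 phosphorylation", ("V_3B", "K_p2"), ("B_n",), (9, 12)),
    FluxInfo("R13", "nuclear BMAL1 dephosphorylation", ("V_4B", "K_dp2"), ("B_np",), (9, 12)),
    FluxInfo("R14", "nuclear phosphorylated BMAL1 degradation", ("V_dBN", "K_d2"), ("B_np",), (12,)),
    FluxInfo("R15", "Myod1 mRNA formation", ("V_sC", "K_AC", "n1"), ("I_N",), (3, 5)),
    FluxInfo("R16", "Bmal1 mRNA nonspecific degradation", ("k_dmb",), ("M_B",), (4,)),
    FluxInfo("R17", "Myod1 mRNA degradation", ("V_mC", "K_mC"), ("M_my",), (5,)),
    FluxInfo("R18", "Myod1 mRNA nonspecific degradation", ("k_dmc",), ("M_my",), (5,)),
    FluxInfo("R19", "MYOD1 formation", ("k_sC",), ("M_my",), (7,)),
    FluxInfo("R20", "cytosolic MYOD1 phosphorylation", ("V_1C", "K_p3"), ("MY_C",), (7, 8)),
    FluxInfo("R21", "cytosolic MYOD1 dephosphorylation", ("V_2C", "K_dp3"), ("MY_cp",), (7, 8)),
    FluxInfo("R22", "cytosolic MYOD1 degradation", ("k_dnc",), ("MY_C",), (7,)),
    FluxInfo("R23", "cytosolic phosphorylated MYOD1 degradation", ("V_dCC", "K_d3"), ("MY_cp",), (8,)),
    FluxInfo("R24", "cytosolic phosphorylated MYOD1 nonspecific degradation", ("k_dn4",), ("MY_cp",), (8,)),
    FluxInfo("R25", "Clock gene production", ("d5",), (), (2,)),
    FluxInfo("R26", "Clock gene degradation", ("d6",), ("G_C",), (2,)),
    FluxInfo("R27", "Clock mRNA formation", ("V_s", "K_I", "m2"), ("P_N",), (2, 6)),
    FluxInfo("R28", "Clock mRNA degradation", ("V_m", "K_m"), ("M_P",), (6,)),
    FluxInfo("R29", "CLOCK (P0) formation", ("k_s",), ("M_P",), (13,)),
    FluxInfo("R30", "P0 phosphorylation", ("V_1", "K_1"), ("P0",), (13, 14)),
    FluxInfo("R31", "P1 dephosphorylation", ("V_2", "K_2"), ("P1",), (13, 14)),
    FluxInfo("R32", "P1 phosphorylation", ("V_3", "K_3"), ("P1",), (14, 15)),
    FluxInfo("R33", "P2 dephosphorylation", ("V_4", "K_4"), ("P2",), (14, 15)),
    FluxInfo("R34", "P2 degradation", ("V_d", "K_vd"), ("P2",), (15,)),
    FluxInfo("R35", "CLOCK entry into the nucleus", ("k5",), ("P2",), (15, 16)),
    FluxInfo("R36", "CLOCK exit from the nucleus", ("k6",), ("P_N",), (15, 16)),
    FluxInfo("R37", "miR-206 formation", ("V_sM", "K_AM", "n2", "C1"), ("MY_C",), (18,)),
    FluxInfo("R38", "R_ISC complex formation", ("C3",), ("miR", "M_P"), (6, 18, 19)),
    FluxInfo("R39", "miR-206 degradation", ("C2",), ("miR",), (18,)),
    FluxInfo("R40", "R_ISC complex degradation", ("C4",), ("R_ISC",), (19,)),
    FluxInfo("R41", "I_N complex formation", ("k3",), ("P_N", "B_n"), (9, 16, 17)),
    FluxInfo("R42", "I_N complex dissociation", ("k4",), ("I_N",), (9, 16, 17)),
    FluxInfo("R43", "I_N complex degradation", ("V_dIN", "K_d4"), ("I_N",), (17,)),
    FluxInfo("R44", "I_N complex nonspecific degradation", ("k_dn5",), ("I_N",), (17,)),
    FluxInfo("R45", "nuclear phosphorylated BMAL1 nonspecific degradation", ("k_dn6",), ("B_np",), (12,)),
    FluxInfo("R46", "Bmal1 gene production", ("d1",), (), (1,)),
    FluxInfo("R47", "Bmal1 gene degradation", ("d2",), ("G_B",), (1,)),
    FluxInfo("R48", "Myod1 gene production", ("d3",), (), (3,)),
    FluxInfo("R49", "Myod1 gene degradation", ("d4",), ("G_M",), (3,)),
)

FLUX_IDS: tuple[str, ...] = tuple(f.id for f in FLUXES)
N_FLUXES = len(FLUXES)
assert N_FLUXES == 49, "flux registry must contain exactly 49 reactions"

_FLUX_IDX = {f.id: i for i, f in enumerate(FLUXES)}

#: signed incidence of the 49 fluxes on the 19 species:
#: species -> {flux id: +1 (produces) or -1 (consumes)}
STOICHIOMETRY: dict[str, dict[str, int]] = {
    "G_B": {"R46": +1, "R47": -1, "R1": -1},
    "G_C": {"R25": +1, "R26": -1, "R27": -1},
    "G_M": {"R48": +1, "R49": -1, "R15": -1},
    "M_B": {"R1": +1, "R2": -1, "R16": -1},
    "M_my": {"R15": +1, "R17": -1, "R18": -1},
    "M_P": {"R27": +1, "R28": -1, "R38": -1},
    "MY_C": {"R19": +1, "R20": -1, "R21": +1, "R22": -1},
    "MY_cp": {"R20": +1, "R21": -1, "R23": -1, "R24": -1},
    "B_c": {"R3": +1, "R4": -1, "R5": +1, "R6": -1, "R9": -1, "R10": +1},
    "B_cp": {"R4": +1, "R5": -1, "R7": -1, "R8": -1},
    "B_n": {"R9": +1, "R10": -1, "R11": -1, "R12": -1, "R13": +1,
            "R41": -1, "R42": +1},
    "B_np": {"R12": +1, "R13": -1, "R14": -1, "R45": -1},
    "P0": {"R29": +1, "R30": -1, "R31": +1},
    "P1": {"R30": +1, "R31": -1, "R32": -1, "R33": +1},
    "P2": {"R32": +1, "R33": -1, "R34": -1, "R35": -1, "R36": +1},
    "P_N": {"R35": +1, "R36": -1, "R41": -1, "R42": +1},
    "I_N": {"R41": +1, "R42": -1, "R43": -1, "R44": -1},
    "miR": {"R37": +1, "R38": -1, "R39": -1},
    "R_ISC": {"R38": +1, "R40": -1},
}


def _hill_repression(V: float, K: float, n: float, x):
    """V * K^n / (K^n + x^n): transcription repressed by x."""
    Kn = K ** n
    return V * Kn / (Kn + x ** n)


def _hill_activation(V: float, K: float, n: float, x):
    """V * x^n / (K^n + x^n): transcription activated by x."""
    xn = x ** n
    return V * xn / (K ** n + xn)


def _mm(V: float, K: float, x):
    """Michaelis-Menten rate V*x/(K+x)."""
    return V * x / (K + x)


def make_rhs(params: ParameterSet, clamp_negative: bool = True) -> Callable:
    """Compile the right-hand side d(state)/dt for a fixed parameter set.

    Returns ``f(t, y) -> dy`` with ``y`` of length 19 (nM) and ``dy`` in
    nM/h.  The system is non-negativity preserving analytically; with
    ``clamp_negative`` (default) small negative excursions from solver
    round-off are clamped to zero before evaluating, otherwise they
    raise ``ValueError``.
    """
    p = params

    def f(t: float, y: np.ndarray) -> np.ndarray:
        if clamp_negative:
            y = np.maximum(y, 0.0)
        elif np.any(np.asarray(y) < 0):
            raise ValueError("negative state component passed to rhs")
        (G_B, G_C, G_M, M_B, M_my, M_P, MY_C, MY_cp, B_c, B_cp, B_n, B_np,
         P0, P1, P2, P_N, I_N, miR, R_ISC) = y

        bmal1_tx = _hill_repression(p.V_sB, p.K_IB, p.m1, I_N)
        clock_tx = _hill_repression(p.V_s, p.K_I, p.m2, P_N)
        myod1_tx = _hill_activation(p.V_sC, p.K_AC, p.n1, I_N)
        risc_form = p.C3 * miR * M_P
        in_form = p.k3 * P_N * B_n

        dy = np.empty(19)
        dy[0] = p.d1 - p.d2 * G_B - bmal1_tx
        dy[1] = p.d5 - p.d6 * G_C - clock_tx
        dy[2] = p.d3 - p.d4 * G_M - myod1_tx
        dy[3] = bmal1_tx - _mm(p.V_mB, p.K_mB, M_B) - p.k_dmb * M_B
        dy[4] = myod1_tx - _mm(p.V_mC, p.K_mC, M_my) - p.k_dmc * M_my
        dy[5] = clock_tx - _mm(p.V_m, p.K_m, M_P) - risc_form
        dy[6] = (-_mm(p.V_1C, p.K_p3, MY_C) + _mm(p.V_2C, p.K_dp3, MY_cp)
                 - p.k_dnc * MY_C + p.k_sC * M_my)
        dy[7] = (_mm(p.V_1C, p.K_p3, MY_C) - _mm(p.V_2C, p.K_dp3, MY_cp)
                 - p.k_dn4 * MY_cp - _mm(p.V_dCC, p.K_d3, MY_cp))
        dy[8] = (-_mm(p.V_1B, p.K_p1, B_c) + _mm(p.V_2B, p.K_dp1, B_cp)
                 + p.k_sB * M_B + p.k2 * B_n - p.k1 * B_c - p.k_dn1 * B_c)
        dy[9] = (_mm(p.V_1B, p.K_p1, B_c) - _mm(p.V_2B, p.K_dp1, B_cp)
                 - p.k_dn2 * B_cp - _mm(p.V_dBC, p.K_d1, B_cp))
        dy[10] = (-_mm(p.V_3B, p.K_p2, B_n) + _mm(p.V_4B, p.K_dp2, B_np)
                  + p.k1 * B_c + p.k4 * I_N - in_form - p.k2 * B_n
                  - p.k_dn3 * B_n)
        dy[11] = (_mm(p.V_3B, p.K_p2, B_n) - _mm(p.V_4B, p.K_dp2, B_np)
                  - p.k_dn6 * B_np - _mm(p.V_dBN, p.K_d2, B_np))
        dy[12] = p.k_s * M_P - _mm(p.V_1, p.K_1, P0) + _mm(p.V_2, p.K_2, P1)
        dy[13] = (_mm(p.V_1, p.K_1, P0) - _mm(p.V_2, p.K_2, P1)
                  - _mm(p.V_3, p.K_3, P1) + _mm(p.V_4, p.K_4, P2))
        dy[14] = (-_mm(p.V_d, p.K_vd, P2) + _mm(p.V_3, p.K_3, P1)
                  - _mm(p.V_4, p.K_4, P2) + p.k6 * P_N - p.k5 * P2)
        dy[15] = -p.k6 * P_N + p.k5 * P2 + p.k4 * I_N - in_form
        dy[16] = in_form - p.k4 * I_N - _mm(p.V_dIN, p.K_d4, I_N) - p.k_dn5 * I_N
        dy[17] = (_hill_activation(p.V_sM, p.K_AM, p.n2, MY_C) + p.C1
                  - p.C2 * miR - risc_form)
        dy[18] = risc_form - p.C4 * R_ISC
        return dy

    return f


def rhs(t: float, state, params: ParameterSet, clamp_negative: bool = True) -> np.ndarray:
    """Time derivative of the 19-species state (nM/h). See ``make_rhs``."""
    return make_rhs(params, clamp_negative=clamp_negative)(t, np.asarray(state, float))


def make_flux_evaluator(params: ParameterSet, clamp_negative: bool = True) -> Callable:
    """Compile a function mapping a state (or state matrix) to the 49 fluxes.

    The returned callable accepts a state of shape ``(19,)`` or
    ``(19, n)`` and returns fluxes of shape ``(49,)`` or ``(49, n)``
    in nM/h; all fluxes are non-negative rates.
    """
    p = params

    def evaluate(y) -> np.ndarray:
        y = np.asarray(y, float)
        if clamp_negative:
            y = np.maximum(y, 0.0)
        elif np.any(y < 0):
            raise ValueError("negative state component passed to flux evaluator")
        s = {name: y[i] for i, name in enumerate(SPECIES)}
        shape = (N_FLUXES,) + y.shape[1:]
        out = np.empty(shape)
        out[_FLUX_IDX["R1"]] = _hill_repression(p.V_sB, p.K_IB, p.m1, s["I_N"])
        out[_FLUX_IDX["R2"]] = _mm(p.V_mB, p.K_mB, s["M_B"])
        out[_FLUX_IDX["R3"]] = p.k_sB * s["M_B"]
        out[_FLUX_IDX["R4"]] = _mm(p.V_1B, p.K_p1, s["B_c"])
        out[_FLUX_IDX["R5"]] = _mm(p.V_2B, p.K_dp1, s["B_cp"])
        out[_FLUX_IDX["R6"]] = p.k_dn1 * s["B_c"]
        out[_FLUX_IDX["R7"]] = _mm(p.V_dBC, p.K_d1, s["B_cp"])
        out[_FLUX_IDX["R8"]] = p.k_dn2 * s["B_cp"]
        out[_FLUX_IDX["R9"]] = p.k1 * s["B_c"]
        out[_FLUX_IDX["R10"]] = p.k2 * s["B_n"]
        out[_FLUX_IDX["R11"]] = p.k_dn3 * s["B_n"]
        out[_FLUX_IDX["R12"]] = _mm(p.V_3B, p.K_p2, s["B_n"])
        out[_FLUX_IDX["R13"]] = _mm(p.V_4B, p.K_dp2, s["B_np"])
        out[_FLUX_IDX["R14"]] = _mm(p.V_dBN, p.K_d2, s["B_np"])
        out[_FLUX_IDX["R15"]] = _hill_activation(p.V_sC, p.K_AC, p.n1, s["I_N"])
        out[_FLUX_IDX["R16"]] = p.k_dmb * s["M_B"]
        out[_FLUX_IDX["R17"]] = _mm(p.V_mC, p.K_mC, s["M_my"])
        out[_FLUX_IDX["R18"]] = p.k_dmc * s["M_my"]
        out[_FLUX_IDX["R19"]] = p.k_sC * s["M_my"]
        out[_FLUX_IDX["R20"]] = _mm(p.V_1C, p.K_p3, s["MY_C"])
        out[_FLUX_IDX["R21"]] = _mm(p.V_2C, p.K_dp3, s["MY_cp"])
        out[_FLUX_IDX["R22"]] = p.k_dnc * s["MY_C"]
        out[_FLUX_IDX["R23"]] = _mm(p.V_dCC, p.K_d3, s["MY_cp"])
        out[_FLUX_IDX["R24"]] = p.k_dn4 * s["MY_cp"]
        out[_FLUX_IDX["R25"]] = np.broadcast_to(p.d5, shape[1:]) if y.ndim > 1 else p.d5
        out[_FLUX_IDX["R26"]] = p.d6 * s["G_C"]
        out[_FLUX_IDX["R27"]] = _hill_repression(p.V_s, p.K_I, p.m2, s["P_N"])
        out[_FLUX_IDX["R28"]] = _mm(p.V_m, p.K_m, s["M_P"])
        out[_FLUX_IDX["R29"]] = p.k_s * s["M_P"]
        out[_FLUX_IDX["R30"]] = _mm(p.V_1, p.K_1, s["P0"])
        out[_FLUX_IDX["R31"]] = _mm(p.V_2, p.K_2, s["P1"])
        out[_FLUX_IDX["R32"]] = _mm(p.V_3, p.K_3, s["P1"])
        out[_FLUX_IDX["R33"]] = _mm(p.V_4, p.K_4, s["P2"])
        out[_FLUX_IDX["R34"]] = _mm(p.V_d, p.K_vd, s["P2"])
        out[_FLUX_IDX["R35"]] = p.k5 * s["P2"]
        out[_FLUX_IDX["R36"]] = p.k6 * s["P_N"]
        out[_FLUX_IDX["R37"]] = _hill_activation(p.V_sM, p.K_AM, p.n2, s["MY_C"]) + p.C1
        out[_FLUX_IDX["R38"]] = p.C3 * s["miR"] * s["M_P"]
        out[_FLUX_IDX["R39"]] = p.C2 * s["miR"]
        out[_FLUX_IDX["R40"]] = p.C4 * s["R_ISC"]
        out[_FLUX_IDX["R41"]] = p.k3 * s["P_N"] * s["B_n"]
        out[_FLUX_IDX["R42"]] = p.k4 * s["I_N"]
        out[_FLUX_IDX["R43"]] = _mm(p.V_dIN, p.K_d4, s["I_N"])
        out[_FLUX_IDX["R44"]] = p.k_dn5 * s["I_N"]
        out[_FLUX_IDX["R45"]] = p.k_dn6 * s["B_np"]
        out[_FLUX_IDX["R46"]] = np.broadcast_to(p.d1, shape[1:]) if y.ndim > 1 else p.d1
        out[_FLUX_IDX["R47"]] = p.d2 * s["G_B"]
        out[_FLUX_IDX["R48"]] = np.broadcast_to(p.d3, shape[1:]) if y.ndim > 1 else p.d3
        out[_FLUX_IDX["R49"]] = p.d4 * s["G_M"]
        return out

    return evaluate


def fluxes(state, params: ParameterSet, clamp_negative: bool = True) -> np.ndarray:
    """The 49 reaction fluxes (nM/h) at one state. See ``make_flux_evaluator``."""
    return make_flux_evaluator(params, clamp_negative=clamp_negative)(
        np.asarray(state, float)
    )


def rhs_from_fluxes(state, params: ParameterSet) -> np.ndarray:
    """Reconstruct d(state)/dt as the signed sum of incident fluxes.

    Independent bookkeeping route used to cross-check ``rhs``: for each
    species the derivative is the stoichiometry-weighted sum of the
    registry fluxes, so any term missing from (or duplicated in) the
    flux registry shows up as a mismatch with ``rhs``.
    """
    v = fluxes(state, params)
    dy = np.zeros(N_SPECIES)
    for sp, incident in STOICHIOMETRY.items():
        i = _IDX[sp]
        for fid, sign in incident.items():
            dy[i] += sign * v[_FLUX_IDX[fid]]
    return dy


def flux_table() -> "pandas.DataFrame":
    """Machine-readable registry of the 49 fluxes.

    Columns: flux id, reaction name, rate-equation numbers of origin,
    participating species and rate constants.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "flux": [f.id for f in FLUXES],
            "name": [f.name for f in FLUXES],
            "equations": [";".join(map(str, f.equations)) for f in FLUXES],
            "species": [";".join(f.species) for f in FLUXES],
            "parameters": [";".join(f.params) for f in FLUXES],
        }
    )
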