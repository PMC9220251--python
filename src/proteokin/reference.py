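"""Synthetic reference parameter sets for the four modulator archetypes.

These are *synthetic* parameter sets: configuration constants chosen so
that the generated assays reproduce the qualitative phenotypes of the four
porphyrinoid archetypes (competitive inhibitors of two affinities, a
biphasic activator/competitive corrole, a pure allosteric activator) with
realistic magnitudes. The two printed dissociation constants
(KI_H2T4_M = 3.6e-7 M, KI_MTPYAPI_M = 1.4e-6 M) and the corrole's
competitive association constant K_AI = 1e6 M^-1 are literature values;
everything else is a synthetic stand-in and must not be read as a measured
quantity. Every generated fixture manifest records which set produced it.
"""

from __future__ import annotations

from .twostate import TwoStateParameters

__all__ = [
    "BASELINE_KCAT_PER_S",
    "BASELINE_KM_M",
    "ENZYME_CONC_M",
    "KI_H2T4_M",
    "KI_MTPYAPI_M",
    "TMPC_LIKE",
    "TRIS_T4_LIKE",
]

#: Baseline turnover number for fixtures, s^-1 (synthetic; fits are
#: scale-consistent in this value because the AMC calibration is implicit).
BASELINE_KCAT_PER_S = 1.0

#: Baseline Michaelis constant for Suc-LLVY-AMC, M (synthetic default).
BASELINE_KM_M = 3.6e-5

#: 20S core particle concentration used in the assays, M.
ENZYME_CONC_M = 2e-9

#: Competitive dissociation constant of the tetra-cationic porphyrin, M.
KI_H2T4_M = 3.6e-7

#: Competitive dissociation constant of the porphyrin-apidaecin hybrid, M.
KI_MTPYAPI_M = 1.4e-6

#: Biphasic corrole archetype: three concerted allosteric sites shift the
#: enzyme to a more efficient B state (activation peaking below 0.5 µM),
#: while one competitive site (K_AI = 1e6 M^-1) dominates above ~1 µM and
#: drives net inhibition. Synthetic set; obeys detailed balance
#: (km_b = km_a * l_u / l_l).
TMPC_LIKE = TwoStateParameters(
    kcat_a=1.0,
    kcat_b=0.6,
    km_a=3.6e-5,
    km_b=9.0e-6,
    l_u=0.1,
    l_l=0.4,
    k_au=2.0e6,
    k_al=3.0e6,
    k_bu=4.0e6,
    k_bl=6.0e6,
    k_ai=1.0e6,
    k_bi=3.0e6,
    n_sites=3,
    m_sites=1,
)

#: Pure allosteric activator archetype: same substrate-linked parameters
#: as TMPC_LIKE (kcat_a/b, km_a/b, l_u, l_l are porphyrin-independent),
#: a ~30-fold lower K_AL, 2-3-fold lower B-state constants, and no
#: competitive site. Synthetic set.
TRIS_T4_LIKE = TwoStateParameters(
    kcat_a=1.0,
    kcat_b=0.6,
    km_a=3.6e-5,
    km_b=9.0e-6,
    l_u=0.1,
    l_l=0.4,
    k_au=1.0e6,
    k_al=1.0e5,
    k_bu=1.6e6,
    k_bl=2.4e6,
    k_ai=0.0,
    k_bi=0.0,
    n_sites=3,
    m_sites=0,
)
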