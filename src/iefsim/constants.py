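"""Physical constants and the reference cytoplasm parameter set.

All dynamics run in SI units (metres, seconds, kilograms, coulombs);
cell geometry is specified in micrometres and converted at the module
boundary through :data:`UM`.
"""

import math

#: Boltzmann constant (J/K).
K_BOLTZMANN = 1.380649e-23

#: Coulomb constant k = 1/(4 pi eps0) (N m^2 / C^2).
K_COULOMB = 8.9875517873681764e9

#: Elementary charge (C).
E_CHARGE = 1.602176634e-19

#: Micrometre in metres.
UM = 1e-6

#: Relative permittivity of cytosol (water-like).
EPSILON_R = 80.0

# ---------------------------------------------------------------------------
# REF-1: reference cytoplasm parameter set.
#
# Effective crowded-cytoplasm viscosity, body temperature, a 5 nm Stokes
# radius and a ~50 kDa protein mass give the drag constant and diffusion
# coefficient via Stokes' law and Einstein-Stokes.  The nuclear charge is
# calibrated so a -2e particle's terminal velocity at r = 4 um is 200 um/s,
# which puts the drift-dominated CM->NM transit at ~0.01 s while leaving the
# diffusion-only mean first passage near 19 s.
# ---------------------------------------------------------------------------

#: Effective cytoplasmic viscosity (Pa s).
ETA_CYTOPLASM = 0.3

#: Temperature (K).
TEMPERATURE = 310.0

#: Stokes radius of a generic messenger protein (m).
STOKES_RADIUS = 5e-9

#: Mass of a generic ~50 kDa messenger protein (kg).
PROTEIN_MASS = 8.3e-23

#: Nuclear point charge (C), cytoplasm-facing positive.
Q_NUCLEUS = 2.513e-12

#: Integration time step (s).
DT = 1e-4

#: Stokes drag constant b = 6 pi eta r for the reference protein (kg/s).
DRAG_B = 6.0 * math.pi * ETA_CYTOPLASM * STOKES_RADIUS

#: Einstein-Stokes diffusion coefficient for the reference protein (m^2/s).
DIFFUSION_D = K_BOLTZMANN * TEMPERATURE / DRAG_B

#: Default cell geometry (um).
R_NUCLEUS_UM = 3.0
R_CELL_UM = 5.0

#: Default radial pH anchors.
PH_NM = 7.2
PH_CM = 7.4
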