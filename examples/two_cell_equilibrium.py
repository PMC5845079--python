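"""Two-cell mechanical balance: where attraction meets contact repulsion.

Builds the calibrated default parameter set, solves the two-cell
equilibrium and prints the derived constants.  The equilibrium overlap
(~2 um) is the indentation at which the strain-energy signal a cell
receives from its partner equals the contact energy pushing them apart;
the total stimulus there (~0.026 kg.um/min^2) is the value against
which the division/mutation/death gates (0.03/0.05/0.1) are compared.
"""

from isletsim import ModelParams, detection_threshold, equilibrium_overlap
from isletsim.contact import contact_energy
from isletsim.mechanics import pairwise_energy

params = ModelParams()
print(f"calibrated traction force F      = {params.F:.4e} kg.um/min^2")
print(f"strain-energy amplitude M0       = {params.M0:.4e} kg.um/min^2")
print(f"attenuation ratio lambda         = {params.lambda_att:.1f}")
print(f"mobility alpha                   = {params.alpha:.1f} um^3.min/kg")

eps = detection_threshold(params.M0, params.lambda_att, 30.0, params.R)
print(f"signal at the 30-um sensing range = {eps:.3g} kg.um/min^2 (numerically zero)")

h_star = equilibrium_overlap(params)
attraction = pairwise_energy(params.M0, params.lambda_att, 2 * params.R - h_star, params.R)
repulsion = contact_energy(h_star, params.R, params.E_c)
print(f"\nequilibrium overlap h*           = {h_star:.3f} um")
print(f"attraction = contact energy      = {attraction:.3e} ~ {repulsion:.3e}")
print(f"total stimulus at equilibrium    = {params.M0 + attraction:.4f} kg.um/min^2")
print("\nThe total stimulus sits below the 0.03 division gate: a cell in a"
      "\nrelaxed pair still has room to divide, while cells squeezed far past"
      "\nthe equilibrium trip the mutation (0.05) and death (0.1) gates.")
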