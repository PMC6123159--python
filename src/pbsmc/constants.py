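"""Physical constants (MeV-mm-gram units unless noted)."""

PROTON_MASS_MEV = 938.27208816
ELECTRON_MASS_MEV = 0.51099895
#: Bethe prefactor 4*pi*N_A*r_e^2*m_e*c^2, MeV cm^2 / mol
K_BETHE = 0.307075
#: Bohr straggling prefactor 4*pi*N_A*r_e^2*(m_e c^2)^2, MeV^2 cm^2 / mol
BOHR_PREFACTOR = 0.1569
#: transport cutoff: protons below this are stopped and deposit locally
CUTOFF_MEV = 2.0
#: upper edge of the supported proton kinetic-energy band
E_MAX_MEV = 300.0
MEV_TO_J = 1.602176634e-13
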