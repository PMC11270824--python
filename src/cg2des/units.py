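"""Unit conventions and physical constants.

Energies and couplings are wavenumbers (cm^-1), time is femtoseconds,
kinetic rates are ps^-1.  Quantum phases are accumulated as
``2*pi*c * E[cm^-1] * t[fs]`` with the speed of light in cm/fs, so a site at
energy eps oscillates as ``exp(-1j * TWO_PI_C * eps * t)``.
"""

#: Boltzmann constant in cm^-1 / K.
KB_CM = 0.695035

#: Speed of light in cm / fs.
C_CM_FS = 2.9979e-5

#: Angular-frequency conversion factor, rad / (cm^-1 fs).
TWO_PI_C = 2.0 * 3.141592653589793 * C_CM_FS

#: Femtoseconds per picosecond.
FS_PER_PS = 1000.0
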