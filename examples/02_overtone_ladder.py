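"""Anharmonic overtone ladder of a C-H stretching mode.

Transition energies follow Delta G(0->n) = n*omega_e - n(n+1)*omega_e*chi_e,
so each overtone falls short of the harmonic multiple and its wavelength sits
above 1/n of the fundamental - the reason NIR overtone bands crowd toward
longer wavelengths than a harmonic model predicts.
"""

from nirassign import VibrationalMode, overtone_positions

mode = VibrationalMode(omega_e=3100.0, omega_e_chi_e=60.0, group="C-H stretch")
print("n   Delta G (cm^-1)   wavelength (nm)   harmonic nm would be")
for n, wavenumber, nm in overtone_positions(mode, n_max=4):
    harmonic_nm = 1e7 / (n * mode.omega_e)
    print(f"{n}   {wavenumber:10.0f}        {nm:8.0f}          {harmonic_nm:8.0f}")
print("\nThe n=2,3,4 rungs are the first/second/third overtones seen in the"
      " 800-1800 nm region; anharmonicity red-shifts each rung in wavenumber.")
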