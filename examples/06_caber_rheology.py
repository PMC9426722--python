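"""CaBER post-processing: Hencky strain and apparent extensional viscosity.

A synthetic exponentially thinning filament (the signature of a visco-
elastic fluid) yields a viscosity that grows exponentially with strain —
the strain-hardening fingerprint seen for gel-forming emulsions.
"""

import numpy as np

from gastrokin import FilamentTrace, apparent_extensional_viscosity, hencky_strain

lam = 0.05          # relaxation time, s
d0 = 1e-3           # initial filament diameter, m
sigma = 0.03        # surface tension, N/m
t = np.linspace(0.0, 0.25, 400)
trace = FilamentTrace(
    times=t,
    d_mid=d0 * np.exp(-t / (3 * lam)),
    d0=d0,
    surface_tension=sigma,
)

strain = hencky_strain(trace)
res = apparent_extensional_viscosity(trace)
print(f"strain range: {strain.min():.2f} .. {strain.max():.2f}")
print(f"apparent viscosity at strain 0.5: "
      f"{np.interp(0.5, res.strain, res.viscosity):.2f} Pa s")
print(f"apparent viscosity at strain 3.0: "
      f"{np.interp(3.0, res.strain, res.viscosity):.2f} Pa s")
print(f"({res.n_dropped} non-thinning points dropped)")
# The viscosity rising with strain indicates strain hardening: the fluid
# resists elongational flow more strongly as the filament thins.
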