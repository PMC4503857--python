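"""Integrate a synthetic NMR spectrum and plot it with the curves.

Two Gaussian peaks with true areas 1:2 are generated, serialized to
JCAMP-DX, read back, and integrated over caller-chosen regions.  The
reported ratios (smallest region = 1.00) estimate relative proton
counts.
"""

from pathlib import Path

from molcanvas import integration_curve, render_spectrum_svg
from molcanvas.fixtures import gaussian_mixture_spectrum, jcamp_text
from molcanvas.formats import read_jcamp

spec = gaussian_mixture_spectrum([(3.0, 1.0, 0.15), (7.0, 2.0, 0.2)],
                                 domain=(0, 10), n_points=2000)
text = jcamp_text("two-peak demo", spec.x, spec.y, form="dif")
spectrum = read_jcamp(text)

result = integration_curve(spectrum, [(2.5, 3.5), (6.5, 7.5)])
for (x1, x2), area, ratio in zip(result.regions, result.areas,
                                 result.ratios):
    print(f"region {x1}:{x2}  area {area:.4f}  ratio {ratio:.2f}")
# ratios 1.00 : 2.00 recover the generator's true areas within 1%

svg = render_spectrum_svg(spectrum, integration=result)
Path("two_peak_nmr.svg").write_text(svg)
print("wrote two_peak_nmr.svg (inverted x axis, NMR convention)")
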