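"""Decompose a CW nitroxide spectrum into free and bound fractions.

A fast-tumbling free ligand gives three sharp lines; rigidly bound ligand
gives a broad powder-like pattern.  Because spectra are recorded as field
derivatives, the sharp component dominates the raw amplitude even at 9%
abundance — spin fractions follow from double integrals instead.
"""

import dimerdeer as dd

templates = dd.default_templates()
spectrum = dd.mix_spectrum(templates, free_fraction=0.09, snr=100, seed=7)

free_fraction, residual = dd.unmix(spectrum, templates)
peak_ratio = abs(templates.free.amplitude).max() / abs(templates.bound.amplitude).max()

print(f"derivative peak ratio free/bound per spin: {peak_ratio:.0f}x")
print(f"recovered free fraction: {free_fraction:.3f} (truth 0.090)")
print(f"fit residual norm: {residual:.3g}")
# Despite the sharp lines towering over the broad component, the
# double-integral convention recovers the true 9% unbound share.
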