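"""Overlap-subtraction corrections on shared spectral windows.

At late oxidation stages the epoxide methine window at 2.88-2.98 ppm contains,
besides the Z-epoxy-monoene protons, co-resonant peaks of hydroxy-epoxide and
keto-epoxide species.  The pipeline quantifies those contributors first from
their clean windows, predicts their in-window area through the internal
reference, and subtracts it — area bookkeeping, not lineshape fitting.
"""

from oxynmr import (
    LineshapeParams,
    default_catalogue,
    eq1_concentration,
    integrate_window,
    make_timecourse,
    packaged_fixture,
    quantify_spectrum,
    render_spectrum,
)
from oxynmr._lorentz import window_fraction

cat = default_catalogue()
tc = make_timecourse(packaged_fixture(), range(17))
day = 16
sp = render_spectrum(tc.row(day), cat, LineshapeParams(), meta={"day": day})
res = quantify_spectrum(sp, cat)

sig = cat.quantifier_of("Z_EPO_Z_mE")
raw = integrate_window(sp, sig.window)
own = window_fraction(sig.center, *sig.window, 0.002)
naive = eq1_concentration(raw / own, sig.n_protons, res.a_tg)

print(f"window {sig.window} ppm, day {day}")
print(f"  naive (no subtraction):  {naive:6.1f} mmol/mol TG")
print(f"  after corrections:       {res.concentrations['Z_EPO_Z_mE']:6.1f} mmol/mol TG")
print(f"  ground truth:            {tc.row(day)['Z_EPO_Z_mE']:6.1f} mmol/mol TG")
print(f"  contributors subtracted: {', '.join(sig.corrections)}")
print("Without the subtraction the epoxide channel absorbs its co-resonant")
print("neighbours and overestimates; the corrected value recovers the truth.")
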