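"""Forward and inverse vergence calculations for one highly myopic eye.

Builds a single biometry record, predicts the postoperative spectacle
refraction with the SRK/T and Haigis formulas at an implanted power, and
inverts each formula for the power that would hit a -3.0 D target.
"""
from hmiol import (
    Biometry,
    IOLConstants,
    haigis_predict_refraction,
    power_for_refraction,
    srkt_predict_refraction,
)

eye = Biometry(
    axial_length=29.2,          # mm, well into the high-myopia range
    k_flat=43.3,
    k_steep=44.3,               # diopters
    acd_epithelium_to_lens=3.42,
    lens_thickness=4.44,
    corneal_diameter=11.76,     # mm
)
lens = IOLConstants(a_constant=118.0)  # Haigis triple derived automatically

implanted = 8.5  # diopters

srkt = srkt_predict_refraction(eye, implanted, lens)
haigis = haigis_predict_refraction(eye, implanted, lens)

print(f"implanted power: {implanted:+.1f} D")
print(f"SRK/T  predicted refraction: {srkt.predicted_refraction:+.3f} D (ELP {srkt.elp:.3f} mm)")
print(f"Haigis predicted refraction: {haigis.predicted_refraction:+.3f} D (ELP {haigis.elp:.3f} mm)")
print(f"SRK/T long-eye corrected AL: {srkt.intermediates['lcor']:.3f} mm")

for formula in ("SRKT", "HAIGIS"):
    p = power_for_refraction(formula, eye, lens, -3.0)
    print(f"{formula}: power for a -3.00 D target = {p:+.2f} D")

# The two formulas disagree by a fraction of a diopter on the same eye --
# exactly the spread the machine-learning ensemble learns to arbitrate.
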