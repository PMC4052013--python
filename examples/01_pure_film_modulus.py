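"""Compression modulus and phase state of pure monolayers.

Builds two synthetic films at 37 °C — a condensed cholesterol/POPC-like model
membrane and a more expanded single-chain drug film — then computes the
compression modulus C_s⁻¹ = −A·dπ/dA along each isotherm, classifies the
phase state from its maximum, and detects the collapse plateau.
"""

import monofilm as mf

membrane_eos = mf.EOSSpec(model="two_segment", collapse=mf.CollapseSpec(47.0))
drug_eos = mf.EOSSpec(model="two_segment", lift_off_area=115.0, slope1=3.2,
                      slope2=1.15, break_pressure=11.0, collapse=mf.CollapseSpec(41.0))

for name, eos in (("model membrane", membrane_eos), ("drug film", drug_eos)):
    grid = mf.pressure_spaced_area_grid(eos, 0.5, eos.collapse.pi_coll + 5.0, 400, spacing="linear")
    record = mf.generate_pure_isotherm(eos, grid, label=name)
    curve = mf.compression_modulus(record)
    cs_max, pi_at = mf.max_compression_modulus(curve)
    phase = mf.classify_phase(cs_max, pressure_at_max=pi_at)
    collapse = mf.detect_collapse(record)
    print(f"{name}:")
    print(f"  C_s^-1 at 15 mN/m : {curve.at(15.0):7.1f} mN/m")
    print(f"  max C_s^-1        : {cs_max:7.1f} mN/m at pi = {pi_at:.1f} mN/m -> {phase.label}")
    print(f"  collapse pressure : {collapse.pi_coll:7.1f} mN/m")

# A film's phase state follows its modulus maximum: ~100-250 mN/m marks a
# liquid-condensed membrane, below 100 a liquid-expanded (fluid) film.
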