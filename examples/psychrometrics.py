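"""Vapour pressure deficit from temperature and relative humidity.

VPD = WVP_sat(T) - WVP_act is the drying power of the air and the driving
force of evaporative water loss.  The same VPD corresponds to different RH
values at different temperatures, which is why a humidity-selecting animal
that defends a constant VPD must select a *higher* RH when it is warmer.
"""

from humidistat import psychro

for temp_c, rh in [(17.0, 71.20), (22.0, 78.48)]:
    s = psychro.humidity_sample(temp_c, rh)
    print(
        f"T={temp_c:4.1f} C  RH={rh:5.2f}%  WVPsat={s.wvp_sat_kPa:.3f} kPa  "
        f"VPD={s.vpd_kPa:.3f} kPa"
    )

vpd = 0.56
print("\nRH needed to hold VPD at 0.56 kPa:")
for temp_c in (17.0, 22.0):
    print(f"  {temp_c:4.1f} C -> RH {psychro.rh_from_vpd(temp_c, vpd):.2f}%")
# The two RH values differ by ~7.7 percentage points: the behavioural
# signature of temperature-compensating (constant-VPD) humidity selection.
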