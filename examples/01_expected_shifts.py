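"""Which isotopologue should each metabolite show under each tracer?

The pathway atlas walks the atom-mapped transition graph from the infused
molecule and counts surviving heavy atoms.  The one chemistry-specific rule:
the d4-NAM tracer's redox-active 4-position deuterium is lost exactly once,
on incorporation into NAD+, so M+4 NAM makes M+3 NAD+ (and recycled M+3 NAM).
"""

from nadflux import default_map, default_tracers, expected_shift, \
    monitored_isotopologues

pmap = default_map()
trp = default_tracers()["13C11-Trp"]
d4 = default_tracers()["2H4-NAM"]

print("U-13C11-Trp arm (de novo / kynurenine pathway):")
for met in ["Trp", "NFK", "Kyn", "3HK", "3HAA", "QUIN", "NAD+", "NAM"]:
    print(f"  {met:5s} -> M+{expected_shift(trp, met, pmap)}")

print("\n2,4,5,6-2H4-NAM arm (salvage):")
print(f"  NAD+  -> M+{expected_shift(d4, 'NAD+', pmap)}"
      "   (redox-site deuterium lost on incorporation)")
print(f"  NAM   -> M+{expected_shift(d4, 'NAM', pmap, route='infusate')}"
      " infusate / "
      f"M+{expected_shift(d4, 'NAM', pmap, route='consumption')} recycled")

print("\nIsotopologues the pipeline monitors per metabolite (d4-NAM arm):")
for met, shifts in monitored_isotopologues(d4, pmap).items():
    print(f"  {met:6s} {['M+%d' % s for s in shifts]}")
# A shift below the atom count marks atoms lost en route (formate, alanine,
# CO2 on the KP; the redox deuterium at NAD+ incorporation).
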