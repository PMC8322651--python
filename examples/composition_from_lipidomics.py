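"""Convert mass-spec sterol measurements into bilayer compositions.

Sterol lipidomics reports pmol sterol per nmol lipid phosphate; relative
to 1000 pmol phospholipid that converts to mol% as 100·S/(1000+S).  The
composition builder then splits the phospholipid remainder 70:30 into
PC:SM and the PC share 80:20 into POPC:DPPC, and largest-remainder
apportionment realizes integer molecule counts for two equal leaflets.
"""

from cgsterol import (
    realize_counts,
    reference_systems,
    sterol_molpercent,
)

print("Measured cholesterol contents -> mol%:")
for label, content in [("control", 608.0), ("LDL 50", 621.0), ("LDL 250", 760.0)]:
    print(f"  {label:8s} {content:6.1f} pmol/nmol P  ->  "
          f"{sterol_molpercent(content):5.2f} mol%")

print("\nModel bilayer systems (rounded mol% per species):")
for name, comp in reference_systems().items():
    cells = "  ".join(
        f"{sp}:{v:g}" for sp, v in comp.rounded_percents().items()
    )
    print(f"  {name:8s} {cells}")

comp = realize_counts(reference_systems()["control"], 8446)
print("\nControl system realized over 8,446 molecules (per leaflet):")
print(" ", dict(comp.counts_per_leaflet))
print("\nEach leaflet holds half the total; trace 7KC keeps at least one")
print("molecule per leaflet so the oxysterol is never rounded away.")
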