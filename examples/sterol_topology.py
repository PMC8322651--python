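"""Build and serialize the 7-ketocholesterol CG topology.

The oxysterol model is the virtual-site cholesterol topology with the
third ring bead (SC3) replaced by a heavier, more polar SNa bead carrying
the C7 ketone.  The script prints the site table, shows the single-bead
difference from the cholesterol reference, and round-trips the ITP text.
"""

from cgsterol import (
    build_7kc_topology,
    build_chol_reference,
    diff_sites,
    read_topology,
    write_topology,
)

kc7 = build_7kc_topology()
chol = build_chol_reference()

print("7-ketocholesterol site table:")
print(write_topology(kc7))
print(f"total mass: {kc7.total_mass:.2f} u")
print(f"virtual (massless) sites: {sorted(kc7.virtual_site_names())}")
print(f"ring-axis (tilt) vector: {kc7.tilt_vector[0]} -> {kc7.tilt_vector[1]}")

sites = diff_sites(kc7, chol)
print(f"\nsites differing from the cholesterol reference: {sites}")
s7, sc = kc7.sites[2], chol.sites[2]
print(f"  site 3: {sc.bead_type} {sc.mass:.2f} u -> {s7.bead_type} "
      f"{s7.mass:.2f} u (the ketone substitution, +{s7.mass - sc.mass:.2f} u)")

assert read_topology(write_topology(kc7)) == kc7
print("\nITP round trip: exact.")
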