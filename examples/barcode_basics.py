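"""Facet persistence barcodes of two reference point configurations.

A facet bar [birth, death) tracks one maximal simplex: it is born when the
simplex enters the Rips filtration and dies when a cofacet absorbs it.
The hexagon and cuboid below are small enough to read off every event.
"""

from srpersist import facet_barcode, make_cuboid, make_hexagon, rips_from_cloud


def show(name, cloud, f_max):
    cx = rips_from_cloud(cloud, max_dim=3, f_max=f_max)
    bc = facet_barcode(cx)
    print(f"\n{name} (f_max = {f_max} A):")
    for dim in bc.dims:
        bars = bc.by_dim(dim)
        print(f"  dimension {dim}: {len(bars)} bars")
        seen = {}
        for b in bars:
            key = (round(b.birth, 3), round(b.death, 3), b.open_ended)
            seen[key] = seen.get(key, 0) + 1
        for (birth, death, open_), count in sorted(seen.items()):
            tail = "  (still alive at ceiling)" if open_ else ""
            print(f"    {count} x [{birth}, {death}){tail}")


hexagon, _ = make_hexagon(side=2.0)
show("regular hexagon, side 2", hexagon, f_max=4.5)
# six vertices stay isolated until the side length 2 joins them into edges;
# the six edges remain maximal until triangles form at 2*sqrt(3) ~ 3.46 A

cuboid, _ = make_cuboid(a=1.0, b=1.0, c=1.5)
show("1 x 1 x 1.5 cuboid", cuboid, f_max=2.5)
# the 8 short edges (length 1) die when face diagonals (sqrt(2)) complete
# triangles; the 4 vertical edges (1.5) die at sqrt(3.25); no dim-2 bars:
# each triangle is swallowed by a tetrahedron the moment it forms
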