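"""Enumerate vulnerability points: minimal cut sets, single points of
failure, and minimal path sets.

A minimal cut set is a smallest combination of basic-event failures that
brings the whole food system down; order-1 cut sets are single points of
failure.  Path sets are the dual: keep any one of them fully operational
and the system cannot fail.
"""

import foodfta as f

tree = f.load_food_system_tree()

for group in ("general", "donation_reliant"):
    spofs = f.single_points_of_failure(tree, group=group)
    print(f"\n{group}: {len(spofs)} single points of failure, e.g.")
    for ev_id in spofs[:5]:
        print(f"  - {tree.events[ev_id].label}")

# Order-<=3 cut sets for the general population; the classic worked example
# is the walking-distance AND: all three conveyances must fail together.
cuts = f.minimal_cut_sets(tree, group="general", max_order=3)
orders = {}
for c in cuts:
    orders[c.order] = orders.get(c.order, 0) + 1
print(f"\ncut sets up to order 3 (general population): {len(cuts)}, by order {orders}")
target = frozenset({"motor_vehicles_unavailable", "bikes_unavailable",
                    "transit_service_suspended"})
print("contains the three-conveyance cut:",
      any(c.events == target for c in cuts))

paths = f.minimal_path_sets(tree, group="general", max_order=2)
print(f"path sets up to order 2: {len(paths)}")
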