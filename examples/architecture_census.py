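"""Assemble the default two-branch model and audit its parameter census.

The census is the ninth evaluation metric: a deployability statement
about the model alongside its discrimination metrics.
"""

from weanwave import assemble_model

assembled = assemble_model(seed=0)

by_component: dict[str, int] = {}
for name, _, count in assembled.parameter_census:
    component = name.split(".")[0]
    by_component[component] = by_component.get(component, 0) + count

print("parameters by component:")
for component, count in by_component.items():
    print(f"  {component:16s} {count:>12,}")
print(f"  {'total':16s} {assembled.n_parameters:>12,}")

# The total is exactly 17,124,721: two MobileNetV3-Large-0.75 extractors
# (the numeric one widened to a 25-channel stem), the fused-feature MLP
# and the 2160->1280->1 classifier head.
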