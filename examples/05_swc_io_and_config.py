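"""SWC text round trips and pipeline configuration files.

Shows the morphology file format the pipeline writes, and the flat
namespaced YAML configuration with typo-safe loading.
"""

from dendrotrace import PipelineConfig, read_swc, write_swc

text = """\
1 1 10.0 10.0 5.0 4.0 -1
2 3 14.0 10.0 5.0 1.0 1
3 3 18.0 10.0 5.0 0.8 2
4 3 18.0 14.0 5.0 0.6 3
"""
tree = read_swc(text)
print(f"read {len(tree)} points; total cable {tree.cable_length():.1f} um")
print("re-serialized:")
print(write_swc(tree))

config = PipelineConfig(valley_scale_um=1.0, link_max_gap_um=6.0)
print("config as YAML (excerpt):")
print("\n".join(line for line in config.to_yaml().splitlines() if line.startswith(("valley", "link"))))

try:
    PipelineConfig.from_yaml("valey.scale_um: 1.0\n")
except ValueError as exc:
    print(f"\ntypos are rejected at load time: {exc}")
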