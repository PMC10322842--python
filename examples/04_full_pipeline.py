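"""One-command pipeline run: simulate -> score -> filter -> model -> gap ->
correlate, with every table and a report written to an output directory.

Equivalent to `navgap demo --seed 5 --out navgap_demo` on the command line.
"""

from navgap import demo_config, run_pipeline

result = run_pipeline(demo_config(out_dir="navgap_demo", seed=5))

print((result.out_dir / "report.md").read_text())
print("outputs:", sorted(p.name for p in result.out_dir.iterdir()))
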