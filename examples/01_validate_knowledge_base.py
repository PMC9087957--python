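"""Load, lint and deliberately break a guideline knowledge base.

The knowledge base is the machine form of the guideline flowcharts: one
rooted decision chart per working diagnosis plus per-drug dose tables.
Linting catches the bug classes seen in real chart-encoding work, such as
a path that never reaches a generated advice or a dose table with an
uncovered renal-function band.
"""

from empirx import example_kb, dump_kb, load_kb, validate_kb

kb = example_kb()
print(f"knowledge base with {len(kb.diagnoses)} diagnoses:")
for name, pathway in kb.diagnoses.items():
    print(f"  {name}: {len(pathway.nodes)} nodes, root {pathway.root!r}")

report = validate_kb(kb)
print("\nlint:", report)  # 0 violations: every path terminates in an advice,
#                           every advised drug has a covering dose table

# break it: remove the middle eGFR band of one dose table
broken = kb.model_copy(deep=True)
del broken.dose_rules["piperacillin-tazobactam"].rows[1]
print("\nafter deleting the [30, 50) piperacillin-tazobactam band:")
print(validate_kb(broken))  # a band_gap violation names the uncovered range

# round-trip through the YAML serialization
text = dump_kb(kb)
assert load_kb(__import__("yaml").safe_load(text)) == kb
print(f"\nYAML round-trip OK ({len(text)} bytes)")
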