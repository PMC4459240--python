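"""Classify a specimen with the quantitative identification key.

The key walks dichotomous couplets whose conditions are thresholds on body
ratios; when a ratio falls in the gap between two printed ranges the result
is honest ("indeterminate") unless an observer-supplied qualitative trait
resolves the couplet.
"""

from mra import compute_ratios, diagnosis_check, key_classify

# measurements in µm of a hypothetical female
specimen = {
    "hea.b": 620.0, "tb3.l": 450.0, "eye.h": 260.0, "sct.l": 220.0,
    "mss.l": 700.0, "ool.l": 100.0, "eye.d": 430.0, "pdl.flg": 520.0,
    "hea.h": 420.0, "eye.b": 150.0, "mv.l": 230.0, "stv.l": 130.0,
    "gst.l": 900.0,
}
ratios = compute_ratios(specimen)
print("ratios:", {k: round(v, 2) for k, v in sorted(ratios.items())})

result = key_classify(ratios)
print(f"\nkey result: {result.label}")
print("couplet trace:", " -> ".join(f"{c}{b}" for c, b in result.trace))

if result.label.startswith("A."):
    table = diagnosis_check(ratios, result.label)
    n_ok = int(table["inside"].sum())
    print(f"diagnosis check vs {result.label}: {n_ok}/{len(table)} "
          "ratios inside the printed ranges")
    print(table.round(2).to_string())

# a ratio in the gap between two couplets' ranges -> indeterminate,
# resolvable by a qualitative trait
gap = dict(ratios)
gap["pdl.flg:eye.h"] = 2.34  # between 2.25 (calandrae) and 2.43 (cornis)
print("\nwith pdl.flg:eye.h = 2.34 (inter-range gap):",
      key_classify(gap).label)
print("same, knowing the flagellum is clavate:",
      key_classify(gap, {"flagellum_clavate": True}).label)
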