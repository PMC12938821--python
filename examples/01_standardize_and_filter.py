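"""Standardize raw SMILES, compute the 20-descriptor profile, apply filters.

Shows the chemical substrate layer: salt stripping, canonicalization,
descriptor computation and drug-likeness filtering with a per-rule report.
"""

from kinomanifold.chemstore import (
    apply_library_filters,
    compute_descriptors,
    standardize_molecule,
)

raw = [
    "CCO.[Na+].[Cl-]",          # ethanol sodium chloride salt
    "c1ccc2c(c1)ncnc2NCC",      # 4-aminoquinazoline (kinase-like core)
    "CC(=O)Oc1ccccc1C(=O)O",    # aspirin
    "C" * 55,                   # a 55-carbon chain (too heavy)
    "C[Si](C)(C)C",             # silane (element outside the whitelist)
]

mols = [standardize_molecule(s) for s in raw]
print("standardized (salts stripped, canonical form):")
for s, m in zip(raw, mols):
    print(f"  {s[:30]:32s} -> {m.smiles}")

d = compute_descriptors(mols[1])
print("\nquinazoline descriptors (subset of the 20-feature profile):")
for key in ("aromatic_rings", "ring_count", "molecular_weight", "logP", "QED", "hba"):
    print(f"  {key:18s} {d[key]:.3f}")

retained, report = apply_library_filters(mols)
print(f"\nlibrary filters: {report.n_retained}/{report.n_input} retained, "
      f"rejections per rule: {report.rejections}")
# Two molecules violate the drug-likeness policy (molecular weight bound and
# the biologically-relevant-element whitelist); the rest pass every rule.
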