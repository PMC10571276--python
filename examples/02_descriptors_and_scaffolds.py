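"""Physicochemical descriptors, Murcko scaffolds and similarity profiles.

Computes the 10 descriptors for a triglyceride and a drug-like molecule,
summarizes scaffolds over a small set, and shows the maximum-Tanimoto
profile of gut-like molecules against a drug reference set.
"""

from gutperm import compute_descriptors, max_tanimoto_profile, murcko_scaffold, scaffold_set_stats

trilaurin = "CCCCCCCCCCCC(=O)OCC(COC(=O)CCCCCCCCCCC)OC(=O)CCCCCCCCCCC"
ibuprofen_like = "CC(C)Cc1ccc(C(C)C(=O)O)cc1"

for name, smi in [("trilaurin", trilaurin), ("arylpropionic acid", ibuprofen_like)]:
    d = compute_descriptors(smi)
    print(f"{name:>20}: mw={d.mw:7.1f}  logp={d.logp:5.2f}  rb={d.rb:2d}  "
          f"hba={d.hba}  hbd={d.hbd}  nring={d.nring}  fsp3={d.fsp3:.2f}")
    print(f"{'scaffold':>20}: {murcko_scaffold(smi)}")

# The triglyceride is heavy, lipophilic, flexible and ringless (no
# scaffold) — the profile of gut-lingering fatty lipids; the aryl acid has
# the compact aromatic frame typical of absorbed drugs.

stats = scaffold_set_stats(["c1ccccc1", "Cc1ccccc1", "c1ccncc1", "CCCCCC"])
print(f"\nscaffold stats: {stats.n_unique_scaffolds} unique frameworks, "
      f"{stats.pct_mols_with_scaffold:.1f}% of molecules bear one")

profile = max_tanimoto_profile(
    ["OCC(O)C(O)CO", "CCCCCCCCCCCC(=O)O"],           # gut-like queries
    ["CC(C)Cc1ccc(C(C)C(=O)O)cc1", "c1ccc2ncccc2c1"],  # drug reference set
)
print(f"max Tanimoto to drug set: {profile.round(3)}")
# Low values mean the gut molecules occupy chemotypes absent from the
# reference drugs.
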