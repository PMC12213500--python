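"""Parse a few molecules and print their six QEA descriptors.

The descriptor panel — MW, logP, HBA, HBD, nRotB, nArR — is the input
space of the algicide-likeness model.  Each row below is one molecule;
counts are exact integers, MW in g/mol, logP dimensionless.
"""

from algiscore import compute_descriptors, fixture_smiles_set

panel = fixture_smiles_set("small_panel")
print(f"{'id':<18}{'mw':>8}{'logp':>8}{'hba':>5}{'hbd':>5}{'nrotb':>7}{'narr':>6}")
for rec in panel[:8]:
    d = compute_descriptors(rec)
    print(f"{rec.id:<18}{d.mw:>8.2f}{d.logp:>8.2f}{d.hba:>5}{d.hbd:>5}"
          f"{d.nrotb:>7}{d.narr:>6}")
print("\nEach molecule is summarised by these six properties; the QEA "
      "score asks how typical they are of known algicides.")
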