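"""Profile a protein as a precursor of anti-diabetic peptides.

Computes the four profiling statistics against the packaged activity
reference: A (frequency of bioactive fragments in the chain), B (EC50
weighted affinity, here from the literature EC50 fixture), A_E (frequency
of release by the digest) and W = A_E / A (relative release frequency).
"""

from pepdigest import (
    GASTROINTESTINAL_ENZYMES,
    ProteinRecord,
    digest,
    packaged_activity_db,
    parameter_B,
    profile_protein,
)
from pepdigest.activity import merge
from pepdigest.cleavage import resolve_enzymes
from pepdigest.resources import literature_ec50_db

protein = ProteinRecord(
    accession="DEMO2",
    sequence="ILKAAGFVLEKPWTRMKHLNFAAVPLGYEK",
    name="demo precursor",
)
db = merge(packaged_activity_db(), literature_ec50_db())
fragments = digest(protein, resolve_enzymes(GASTROINTESTINAL_ENZYMES))

for cls in db.classes():
    prof, ae = profile_protein(protein, fragments, db, cls)
    w = f"{ae.W:.4f}" if ae.w_defined else "undefined (A = 0)"
    b = f"{prof.B:.6f} /mM" if prof.b_defined else "undefined (no EC50 data)"
    print(f"{cls}:")
    print(f"  A   = {prof.A:.4f}   occurrences of active peptides per residue")
    print(f"  B   = {b}")
    print(f"  A_E = {ae.A_E:.4f}   active peptides actually released per residue")
    print(f"  W   = {w}")
    if ae.released:
        print("  released:", ", ".join(f"{f.sequence} {f.coordinate_label()}" for f in ae.released))

# A high W means the digest is efficient at liberating the activity that
# the intact sequence encodes; A_E <= A always.
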