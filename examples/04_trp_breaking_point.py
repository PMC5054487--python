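"""Predicting the real-world breaking point of tryptophan biosynthesis.

Computes permeability descriptors (MW, TPSA, logP, H-bond counts) for the
seven metabolites of the chorismate -> L-tryptophan pathway from pinned
SMILES, classifies each into permeability classes under the shipped
ruleset, and predicts the pathway breaking point as the most permeable
non-channeled intermediate.

In the aphid Cinara cedri's endosymbiont consortium the pathway is split
exactly there: Buchnera runs chorismate -> anthranilate and Serratia
finishes the synthesis.
"""

import metcomp as mc
from metcomp.permeability import predict_breaking_point, records_to_frame

records = mc.trp_pathway_fixture()
print(records_to_frame(records).round(2).to_string(index=False))

pos = predict_breaking_point(records)
name = next(r.name for r in records if r.position == pos)
print(f"\npredicted breaking point: position {pos} ({name})")

pos_free = predict_breaking_point(records, ignore_channeling=True)
name_free = next(r.name for r in records if r.position == pos_free)
print(f"ignoring substrate channeling: position {pos_free} ({name_free})")

# Indole has the best descriptors (TPSA 15.8), but it is channeled inside
# tryptophan synthase and never free to diffuse, so anthranilate -- the
# other class-H intermediate -- is the predicted (and observed) split.
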