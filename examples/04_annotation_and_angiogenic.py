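"""Annotate cell types by marker argmax and call angiogenic ECs.

Each cell is labeled with the panel cell type whose markers have the
highest mean normalized expression; endothelial cells are then screened
for the activation program (Mki67, Cxcr4, Dll4, Aplnr, Esm1) with a
quantile cutoff.  Against the generator's ground truth this reports the
accuracy of both selection steps.
"""

import coactivate as ca

matrix, truth = ca.simulate_dataset(ca.SyntheticConfig(seed=3, n_cells=2000))
matrix = ca.normalize(matrix)

annotation = ca.annotate_cells(matrix, ca.default_marker_panel())
print("label counts:", dict(annotation.counts()))
accuracy = (annotation.labels == truth.labels).mean()
print(f"annotation accuracy vs truth: {accuracy:.1%}")

ec = ca.select_endothelial(matrix, annotation)
call = ca.call_angiogenic(
    ec, ca.default_signature("Endothelial activation/proliferation"),
    method="quantile", cutoff=0.75,
)
flag = truth.angiogenic_flag.reindex(call.is_angiogenic.index, fill_value=False)
recall = (call.is_angiogenic & flag).sum() / flag.sum()
print(f"angiogenic ECs called: {call.n_angiogenic}/{ec.n_cells} "
      f"(score cutoff {call.cutoff:.2f}); recall vs truth: {recall:.1%}")
print(
    "\nHigh accuracy/recall confirm that marker argmax and the additive "
    "activation score recover the planted cell states."
)
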