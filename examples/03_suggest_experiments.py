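"""Which reactions of a new reagent should be measured first?

t-SNE embeds the candidate reactions of one additive, and Kennard-Stone
ranks them so that the selected set covers the space homogeneously: the
first two are the farthest pair, each next one maximizes its minimum
distance to everything already chosen.
"""

import metarf as mf

dataset, _ = mf.gen_dataset(mf.SynthConfig(seed=0))
group = dataset.group_values()[5]
plan = mf.select_fewshot(dataset, group, n=5, embed_config=mf.EmbeddingConfig(seed=0))

print(f"experiment plan for additive {group} "
      f"({plan.candidate_indices.size} candidates):")
print(plan.to_frame().to_string(index=False))
print("rank = suggested measurement order; coord_* are the t-SNE coordinates")
print("the plan never looks at yields - only at reaction encodings")
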