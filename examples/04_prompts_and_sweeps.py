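"""Prompt strategies and the few-shot / context-length sweeps.

Builds a zero-shot, a few-shot and a knowledge-augmented prompt for the
same mention (printing the few-shot one), then sweeps shot counts and
context-window sizes with the deterministic rule backend on a synthetic
study to show the evaluation tables the harness produces.
"""

import raretext as rt
from raretext.evaluation import metrics_table
from raretext.synthetic import generate_fewshot_bank

bundle = rt.generate_bundle(rt.SynthParams(n_docs=100, seed=1))
mentions = rt.extract_corpus_mentions(
    bundle.documents, rt.build_matcher(bundle.vocabulary)
)
bank = generate_fewshot_bank(bundle, k_max=10, seed=1)

# restrict evaluation to documents outside the bank split (no overlap
# between few-shot examples and the test set)
eval_ids = bundle.eval_doc_ids
eval_mentions = [m for m in mentions if m.doc_id in eval_ids]
gold = rt.GoldSet(
    annotations=[a for a in bundle.gold_set().annotations if a.doc_id in eval_ids]
)

mention = eval_mentions[0]
doc = next(d for d in bundle.documents if d.doc_id == mention.doc_id)
context = rt.extract_context(doc, mention, "sentences", 1)
examples = rt.select_few_shot(bank, 2, seed=3, excluded_doc_ids=eval_ids)
prompt = rt.build_prompt(
    mention, context, rt.PromptStrategy(mode="few_shot", k=2, seed=3), examples
)
print("--- few-shot prompt ---")
print(prompt.text)

kag = rt.build_prompt(
    mention, context, rt.PromptStrategy(mode="kag"),
    definition=rt.lookup_definition(mention.cui, bundle.definitions),
)
print(f"\nkag prompt uses definition: {kag.definition_used}")

backend = rt.RuleBasedBackend(bundle.rule_config())
fs_rows = rt.sweep_few_shot(
    eval_mentions, bundle.documents, gold, backend, bank,
    k_values=(1, 2, 3), seed=0,
)
print("\nfew-shot sweep (rule backend ignores the examples, so the rows "
      "coincide — the sweep harness itself is what is shown):")
print(metrics_table(fs_rows).to_string(index=False))

ctx_rows = rt.sweep_context(
    eval_mentions, bundle.documents, gold, backend, sizes=(25, 200, 0)
)
print("\ncontext sweep (size 0 = whole document):")
print(metrics_table(ctx_rows).to_string(index=False))
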