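"""Cross-species vs. species-specific training.

Here the generator encodes learnable within-species signal (kappa = 0.3).
One model is trained on all species pooled (regime G, lr 1e-4) and one
independent model per species (regime S, lr 1e-3); both use light-attention
pooling, the (128, 64, n) MLP head, AdamW and early stopping on validation
RMSE. The paired t-test compares per-protein absolute errors between the
two regimes.
"""

import tmelt
from tmelt.experiment import ScenarioSpec, train_scenario
from tmelt.evaluation import build_report

cfg = tmelt.SyntheticConfig(
    n_species=6, proteins_per_species=120, embedding_dim=16, length_range=(50, 80),
    kappa=0.3, seed=11,
)
ds = tmelt.generate_dataset(cfg)

records = []
for approach in ("baseline", "dual"):
    for regime in ("G", "S"):
        records.extend(
            train_scenario(
                ds, ScenarioSpec(approach=approach, regime=regime, max_epochs=80, patience=10, seed=0)
            )
        )

report = build_report(records, n_boot=200)
print(report.to_summary_frame().to_string(index=False))
# rmse_S < rmse_G with a significant paired t-test reproduces the central
# observation: species-specific models beat the pooled model even though
# each sees far less data. The dual-loss approach decomposes the
# prediction into a species-level estimate plus a per-protein offset but
# shows the same ordering.
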