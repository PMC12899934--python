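"""Random-forest dietary pattern classification with feature importances.

Trains the 500-tree forest on a 70% stratified split of the default
simulation and reports held-out accuracy, per-class metrics and the
normalized Gini importances of the twelve classification features.
"""
import dietsim
from dietsim.classify import train_pattern_classifier

db = dietsim.default_food_table()
pop = dietsim.simulate_population(db, seed=42)

report = train_pattern_classifier(pop, seed=42)
print(f"held-out accuracy: {report.accuracy:.3f} "
      f"(chance level for 4 balanced classes: 0.25)")
print(f"macro F1 {report.macro_f1:.3f}, weighted F1 {report.weighted_f1:.3f}\n")
for label, m in report.per_class.items():
    print(f"{label:>14}: precision {m.precision:.3f}  recall {m.recall:.3f}  "
          f"F1 {m.f1:.3f}  (n={m.support})")
print("\ntop feature importances (share of total Gini impurity decrease):")
print(report.importances.sort_values("mean", ascending=False).head(5)
      .round(4).to_string())
# Accuracy well above 0.25 shows the footprint/cost/demographic features
# carry real pattern signal; overlap between patterns keeps it far from 1.
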