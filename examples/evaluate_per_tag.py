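"""Per-tag precision/recall/F1 with micro and macro averaging.

Micro averaging pools counts over tags, so frequent tags dominate; macro
takes the unweighted mean over tags with gold support, so one bad rare tag
pulls it down hard — the reason the two can diverge sharply on imbalanced
entity-tag distributions.
"""

from subtag import LabelSequence, Scheme, tag_metrics

gold = LabelSequence(Scheme.WP, ("B-DZ", "I-DZ", "O", "B-SX"))
pred = LabelSequence(Scheme.WP, ("B-DZ", "O", "O", "B-SX"))

report = tag_metrics(gold, pred)
print(f"{'tag':6s} {'tp':>3s} {'fp':>3s} {'fn':>3s} {'prec':>6s} {'rec':>6s} {'f1':>6s}")
for tag, s in report.per_tag.items():
    print(f"{tag:6s} {s.tp:3d} {s.fp:3d} {s.fn:3d} "
          f"{s.prf.precision:6.3f} {s.prf.recall:6.3f} {s.prf.f1:6.3f}")
m = report.micro
print(f"micro  precision {m.precision:.4f}  recall {m.recall:.4f}  f1 {m.f1:.4f}")
m = report.macro
print(f"macro  precision {m.precision:.4f}  recall {m.recall:.4f}  f1 {m.f1:.4f}")
# the missed I-DZ position costs recall (micro r = 2/3) but no precision;
# macro-f1 = mean(1.0, 0.0, 1.0) = 0.667 over the three gold-supported tags
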