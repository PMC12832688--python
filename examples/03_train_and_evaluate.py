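"""Train the network end to end on synthetic phantoms and evaluate.

A scaled-down run: 80 images/class at 48x48, a few epochs.  Prints the
per-epoch history, the best checkpoint, and the held-out test metrics.
Expect a couple of minutes on one CPU.
"""

import numpy as np

from pneunet.data import SplitSpec, SyntheticSpec, generate_synthetic, stack_images, stratified_split
from pneunet.evaluation import confusion, report, roc_auc
from pneunet.model import ArchitectureConfig, build_pneunet
from pneunet.training import TrainConfig, restore, train

SIZE = 48
records = generate_synthetic(SyntheticSpec(n_normal=80, n_pneumonia=80, seed=7))
labels = [r.label for r in records]
tr, va, te = stratified_split(labels, SplitSpec(seed=42))
x, y = stack_images(records, target=SIZE)

net = build_pneunet(ArchitectureConfig(input_height=SIZE, input_width=SIZE), seed=42)
ckpt, hist = train(net, (x[tr], y[tr]), (x[va], y[va]),
                   TrainConfig(max_epochs=6, batch_size=16, seed=42))
for row in hist.to_dataframe().itertuples(index=False):
    print(f"epoch {row.epoch}: train_loss {row.train_loss:.3f} "
          f"train_acc {row.train_acc:.3f} val_loss {row.val_loss:.3f} "
          f"val_acc {row.val_acc:.3f}")
print(f"best epoch {ckpt['best_epoch']} (val loss {ckpt['val_loss_at_best']:.3f})")

restore(net, ckpt)
p = net.predict(x[te])
cm = confusion(y[te], p)
rep = report(cm)
print(f"test confusion: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
print(f"test accuracy {rep.accuracy:.3f}, pneumonia recall "
      f"{rep.pneumonia.recall:.3f}, AUC {roc_auc(y[te], p).auc:.3f}")
print("the recall row is the clinically critical number: the fraction of"
      " pneumonia phantoms the model does not miss.")
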