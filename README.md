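# subnucpred

Ensemble prediction of protein **subnuclear localization** from primary
sequence alone.

A protein sequence is turned into complementary numeric views — reduced
amino-acid alphabet statistics, physicochemical property signals and
signal-analytic descriptors — and an ensemble of pairwise probabilistic
support vector machines, each on its own optimal feature subset, votes the
localization class.

## The method in one paragraph

Eleven feature extractors encode each sequence: local amino-acid and
dipeptide composition over terminal windows (LAAC, LDC), global
composition/transition/distribution descriptors (GD) and Lempel-Ziv
complexity (LZC) over 20 reduced amino-acid alphabets; three
autocorrelation descriptors (AD: Moreau-Broto, Moran, Geary),
autocovariance (AC), sequence-order descriptors (SD: coupling numbers +
quasi-sequence-order) and a property distribution descriptor (PPDD) over
~30 physicochemical scales; and recurrence quantification (RQA), discrete
wavelet statistics (DWT) and Hilbert-Huang spectral features (HHT) over
property-encoded signals.  For every unordered class pair a two-step
mRMR + incremental-feature-selection search picks an optimal feature
subset and SVM parameters (the RBF width can be chosen automatically from
the data: gamma = 1/(2·sigma²) with sigma the mean pairwise distance); a
probabilistic binary SVM is trained per pair, the pairwise probabilities
are coupled into a class-probability vector (Wu-Lin-Weng), and a second,
conventional multiclass SVM over those vectors makes the final call.
Unbalanced classes are handled by weighting each class by
largest-class-size / class-size.

## Worked example

Everything below runs offline on synthetic data (the package ships a
generator; see `docs/methods.md` for its scope and limits).

```bash
# 1. simulate a 4-class dataset (120 sequences)
subnucpred simulate --k 4 --n-per-class 30 --seed 20130227 \
    --fasta demo/data.fasta --labels demo/data.tsv
# wrote 120 sequences, 4 classes

# 2. extract features into a wide TSV
subnucpred extract --fasta demo/data.fasta --methods laac,gd \
    --out demo/features.tsv
# wrote 120 x 1661 features to demo/features.tsv

# 3. train the two-stage ensemble (per-pair feature selection included)
subnucpred train --fasta demo/data.fasta --labels demo/data.tsv \
    --methods laac,gd --cap 40 --model-out demo/model.pkl
# trained 6 pair models; wrote demo/model.pkl

# 4. predict
subnucpred predict --model demo/model.pkl --fasta demo/data.fasta \
    --out demo/predictions.tsv

# 5. leave-one-out evaluation (selection redone on every turn, no leakage)
subnucpred evaluate --fasta demo/data.fasta --labels demo/data.tsv \
    --methods laac,gd --cap 40 --out demo/evaluation.json
# LOOCV overall accuracy: 0.992
```

Or all stages at once: `subnucpred pipeline --workdir demo`.

The same pipeline from Python:

```python
import numpy as np
from subnucpred import (EnsembleConfig, ExtractionConfig, default_fixture,
                        extract_blocks, train_two_stage)

ds = default_fixture()                       # 4 classes x 30 sequences
blocks, names = extract_blocks(ds, ExtractionConfig(methods=("laac", "gd")))
y = np.array([next(iter(r.labels)) for r in ds.records])
model = train_two_stage(blocks, y, EnsembleConfig(cap=40, C_grid=(0.5, 8.0, 128.0)))
labels, proba = model.predict(blocks)        # proba rows sum to 1
```

## Layout

| Path | Contents |
| --- | --- |
| `src/subnucpred/alphabets.py` | 20 reduced amino-acid alphabets |
| `src/subnucpred/comp_features.py` | LAAC, LDC, GD, LZC extractors |
| `src/subnucpred/physchem_features.py` | AD, AC, SD, PPDD extractors |
| `src/subnucpred/signal_features.py` | RQA, DWT, EMD/HHT extractors |
| `src/subnucpred/selection.py` | mRMR ranking + incremental feature selection |
| `src/subnucpred/ensemble.py` | two-stage pairwise SVM ensemble, GFO, coupling |
| `src/subnucpred/evaluation.py` | metrics, ROC, jackknife/k-fold, randomization analyses |
| `src/subnucpred/synthetic.py` | synthetic dataset generator |
| `src/subnucpred/data/` | property scales, distance matrices, alphabet table |
| `docs/methods.md` | model assumptions, parameter choices, data provenance |

See `docs/methods.md` for every numerical convention, default and known
limitation, including which packaged data are authentic and which are
clearly-labeled synthetic stand-ins.
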