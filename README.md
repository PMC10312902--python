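# seq2loc

Sequence-to-localization image generation: predict the subcellular
distribution of a protein as a per-pixel probability map, from its amino-acid
sequence and a reference nucleus image.

Most localization predictors emit a discrete compartment label. `seq2loc`
instead treats the task as conditional image generation, which naturally
captures multi-compartment proteins and cell-state context carried by the
reference morphology:

* two **vector-quantized image codecs** tokenize the nucleus reference
  channel and the mean-threshold-binarized protein channel into grids of
  codebook indices;
* a **decoder-only autoregressive transformer** models the joint stream
  `[START] ⊕ amino-acid embeddings ⊕ reference tokens ⊕ protein tokens`
  (start token prepended, final protein token removed from the input), with
  frozen per-residue sequence embeddings and learned image-token embeddings;
* at inference the protein tokens are sampled (top-quartile logit filter +
  Gumbel-max), and the per-token probabilities p(vᵢ) weight a convex
  combination **v̄ = Σᵢ wᵢ p(vᵢ)** of codebook vectors that decodes into a
  continuous probability density map;
* **attention-difference attribution** contrasts the attention that each
  residue receives from protein-present versus protein-absent generated
  patches, nominating sequence motifs (e.g. nuclear localization signals)
  that drive the predicted localization.

Because training on a real paired corpus needs GPU-scale resources, the
package ships a first-class **synthetic cell-image benchmark**: paired
nucleus/protein images whose localization class (nuclear / cytoplasmic /
peripheral / diffuse) is deterministically planted as a sequence motif
(`KKKRKV` → nuclear, `LLVVLL` → peripheral). Every stage — tokenizers,
transformer, metrics, attribution — is trained and validated end to end on
this benchmark, on one CPU, in minutes. See `docs/methods.md` for the full
model description and design decisions.

## Worked example

```bash
# 1. generate a synthetic benchmark (240 samples, 4 balanced classes)
seq2loc simulate --out data --n 240 --seed 7

# 2. train codecs + transformer (mini preset, one CPU)
seq2loc train-transformer --dataset data --out ckpt --seed 0 --steps 2400

# 3. score localization metrics on the held-out split
seq2loc evaluate --dataset data --checkpoint ckpt --split val --out report.csv

# 4. predict and attribute a single sequence
seq2loc predict --fasta query.fasta --reference nucleus.png \
                --checkpoint ckpt --seed 1 --out pred/
seq2loc attribute --fasta query.fasta --reference nucleus.png \
                  --checkpoint ckpt --out attr/
```

Running this study end to end (the `--seed 1` reproduction below) prints

```
[acceptance] overfit CE = 3.679e-06 (85.3s)
[acceptance] val accuracy=0.900 ceiling=1.000 p=2.99e-05 (5.5s)
[acceptance] motif recovery 1.00 (3.3s)
```

meaning: the token prior can memorize a 16-sample subset essentially
perfectly (3.7 × 10⁻⁶ nats per protein token); on 40 held-out samples the
naive nuclear classifier (in-nucleus map mass ρ ≥ 0.5) matched the planted
ground truth for 90% of samples, below the tokenizer's own ceiling of
100%; NLS-bearing sequences received significantly more in-nucleus
probability mass than NLS-free ones (one-sided Mann-Whitney
p ≈ 3 × 10⁻⁵); and the top attribution segment overlapped the planted
`KKKRKV` motif in 20/20 fresh nuclear sequences.  The `evaluate` CLI stage
writes the per-sample ρ / NPA / IoU / call rows plus a summary row to
`report.csv` (NPA, nucleus proportion accuracy, is 1 − |ρ_pred − ρ_truth|;
this run's validation mean was 0.79).

Library use mirrors the CLI:

```python
from seq2loc import generate_records, train_pipeline, predict
from seq2loc.pipeline import MINI

records = generate_records(240, seed=7, config=MINI.generator)
bundle = train_pipeline(records[:200], MINI, seed=0, steps=2400)
result = predict(records[200].sequence, records[200].reference_image,
                 bundle, seed=1)
result["probability_map"].pixels      # (64, 64) array in [0, 1], peak = 1
```

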