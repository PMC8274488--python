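# opfddl

Optimized projection and Fisher discriminative dictionary learning: a
trainable classifier for signals that arrive as several parallel feature
views ("frequency bands"), such as per-band EEG features in brain–computer
interface emotion recognition.  Instead of concatenating band features into
one long vector, the model learns an orthonormal projection **Q**^r per band
together with **one shared class-structured dictionary**
D = [D₁, …, D_C], coupling the bands in a common subspace while keeping each
band's specific information.

Training minimizes a Fisher criterion on sparse-reconstruction residuals.
With δ_l(s) the part of a code s on its sample's own class atoms and
ζ_l(s) = s − δ_l(s) the rest, the per-band within/between residual scatters

    W_w^r = Σ_j (x_j^r − D δ(s_j^r))(x_j^r − D δ(s_j^r))ᵀ,
    W_b^r = Σ_j (x_j^r − D ζ(s_j^r))(x_j^r − D ζ(s_j^r))ᵀ

enter the quadratic weighted objective

    min_{Q̃, D, μ}  μ² Σ_r tr(Q^rᵀW_w^rQ^r) − μ Σ_r tr(Q^rᵀW_b^rQ^r),
    s.t. Q^rᵀQ^r = I,

solved by alternating closed-form/eigen updates (codes → projections →
dictionary → adaptive weight μ).  A test sample is classified per band by the
smallest least-squares reconstruction error onto each class's projected
sub-dictionary, and the final label is the majority vote across bands.
See `docs/methods.md` for the full model, assumptions and numerical choices.

## Worked example

The package is fully testable from its own synthetic generator, which plants
the structure the model assumes (shared latent class atoms, band-specific
orthonormal lifts, class-sparse codes, exact-SNR Gaussian noise):

```python
from opfddl import SynthConfig, TrainConfig, generate_dataset, fit, evaluate

dataset, truth = generate_dataset(SynthConfig(seed=7))     # C=3, R=3, m=20, n=300, 10 dB
model = fit(dataset, TrainConfig(atoms_per_class=10, seed=7))
acc, confusion = evaluate(dataset, model)
print(len(model.objective_trace), round(model.mu, 4), acc)
print(confusion)
```

```
27 2.4084 0.9833333333333333
[[100   0   0]
 [  1  96   3]
 [  1   0  99]]
```

Training converged in 27 iterations (relative objective change below the
1e-3 threshold), the adaptive Fisher weight settled at μ ≈ 2.41, and 295 of
300 training samples are classified correctly (98.3%); the confusion matrix
rows are the true classes.  On the noiseless variant
(`SynthConfig(seed=7, snr_db=None)`) the same configuration reaches 100%.

The same workflow is available from the shell:

```sh
opfddl --seed 7 simulate --out data.zip
opfddl --seed 7 train --data data.zip --atoms-per-class 10 --model-out model.zip --report run.json
opfddl predict --data data.zip --model model.zip --out predictions.tsv
opfddl evaluate --data data.zip --model model.zip
opfddl --seed 7 sweep --data data.zip --atoms 5,10 --folds 5 --repeats 5 --out sweep.tsv
```

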