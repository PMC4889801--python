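# gfcmnn

A general fuzzy cerebellar-model neural network (GFCMNN) multidimensional
classifier for data described by **intuitionistic fuzzy sets** (IFS), with a
similarity-based decision rule. The package targets small decision-support
problems — the bundled benchmark is a five-disease medical-diagnosis task —
where each observation carries, per feature, a membership degree μ, an
independent nonmembership degree ν, and a hesitation margin π = 1 − μ − ν.

## The model

Each IFS triple is first scalarized by a *score function*:

- membership only: `R = μ`
- score 1: `R = μ − νπ`
- score 2: `R = μ + νπ`
- score 3: `R = μ − ν + 1/(απ + β)` with positive constants α, β
  (defaults 100 and 10)

The resulting feature vector **I** ∈ ℝⁿⁱ enters a CMAC-style associative
memory with `n_j` layers of `n_k` blocks per input. Rule (j,k) holds one
Gaussian receptive field per input, and its activation is the product
inference

    r_jk = ∏ᵢ exp( −(Iᵢ − m_ijk)² / v_ijk² ),

so the o-th category output is the weighted sum `O_o = Σ_jk w_jko · r_jk`.
Weights, means, and variances are trained online by gradient descent on the
squared-error cost `E = ½ Σ_o (d_o − O_o)²` against one-hot targets. A
Lyapunov argument bounds each family's stable learning rate by `2/‖P‖²`
(P = ∂O/∂z) with the optimal rate `1/‖P‖²`; both fixed-rate and adaptive
modes are implemented (`gfcmnn.network.rate_bound`, `optimal_rate`,
`delta_lyapunov`).

Classification treats the clipped output vector as a fuzzy set over the
categories and scores it against each one-hot category pattern with the
fuzzy Jaccard index `|A ∩ B| / |A ∪ B| = Σ min / Σ max`; the argmax wins
(ties to the lowest index).

## Worked example

Train on the five bundled disease prototypes (viral fever, malaria, typhoid,
stomach problem, chest problem; five symptoms each as IFS triples) and
diagnose the four bundled patients with score function 3:

```sh
$ gfcmnn demo-medical --mode score3 --seed 1 --outdir demo
Al: category 2 (Malaria)
Bob: category 4 (Stomach problem)
Joe: category 3 (Typhoid)
Ted: category 2 (Malaria)
trained 3595 epochs; outputs -> demo
```

`demo/similarities.csv` holds the patient-by-disease fuzzy-Jaccard profile
behind those picks — each row's maximum is the predicted disease:

```
sample,Viral fever,Malaria,Typhoid,Stomach problem,Chest problem
Al,0.0715,0.2697,0.2666,0.0131,0.0000
Bob,0.0270,0.0000,0.1798,0.2875,0.1433
Joe,0.0664,0.0752,0.4352,0.0727,0.0000
Ted,0.0540,0.2291,0.1247,0.0590,0.1082
```

All four assignments match the clinician's diagnoses. Initialization is
random, so a single seed can flip a borderline case (Al sits between malaria
and typhoid); `gfcmnn.experiments.majority_medical_predictions` summarizes
over a seed list.

The five-round cross-validation protocol re-splits the nine-sample pool
(5 prototypes + 4 patients), exchanging one diagnosis-matched pair per
round, and scores 20 predictions per run:

```sh
$ gfcmnn crossval --mode score3 --seeds 0,1,2 --outdir cv
seed 0: T=14 N=6 ACC=70.0%
seed 1: T=20 N=0 ACC=100.0%
seed 2: T=19 N=1 ACC=95.0%
median ACC over 3 seeds: 95.0% (median T=19/20)
```

The same machinery is available as a library (`run_medical_example`,
`run_crossval`, `crossval_over_seeds`) and works on any IFS dataset in the
package's CSV/JSON dialects (`gfcmnn transform`, `gfcmnn train`,
`gfcmnn predict`), including synthetic ones from `gfcmnn simulate`.

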