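# taview — retrieving hidden atrial repolarization (Ta) waves from 12-lead ECG

The atrial repolarization wave (Ta) is an early marker of atrial injury and
arrhythmia, but on a normal surface ECG it is buried under the ventricular
QRS complex, which is orders of magnitude stronger. `taview` recovers it by
solving the inverse problem at the source level instead of manipulating
waveforms: it reconstructs transmembrane potentials (TMPs) on a coarse
myocardial surface model from the 8 independent channels of the standard
12-lead ECG and re-projects only the atrial source block back to the body
surface, yielding an atrial-only ECG (P + Ta) with the ventricular
contribution removed by construction.

The package is aimed at computational electrophysiology researchers who want
a fully self-contained, reproducible implementation of this pipeline — every
experiment builds from synthetic geometry and simulated signals with zero
downloads.

## Model

Forward map (lead field): `phi(t) = L u(t)`, with L assembled from the
equivalent-double-layer kernel of the quasi-static Poisson problem and
sampled at the 8 electrode channels {I, II, V1–V6} (III and augmented leads
derived, so II = I + III holds to machine precision).

Source dynamics (two-variable excitation–recovery reaction–diffusion):

    du/dt = div(D grad u) + k u (u − a)(1 − u) − u v
    dv/dt = −e (v + k u (u − a − 1))

State-space data model and hierarchical posterior:

    x_{k+1} = F_theta(x_k) + w_k             w ~ N(0, xi_w I)
    phi_k   = (L + DeltaL) u_k + z_k         z ~ N(0, xi_z I)

    P(x, DeltaL, theta, xi_w, xi_z | phi) ∝
        P(phi | x, DeltaL, xi_z) P(x | theta, xi_w)
        P(DeltaL) P(xi_z) p(theta) P(xi_w)

sampled by blocked Gibbs: exact forward-filter backward-sampling on a
reference linearization of the dynamics (ensemble Kalman smoother available
as an alternative), slice sampling for θ = (k, a, e), and exact conjugate
updates for ΔL (Gaussian) and the noise variances (inverse-gamma). Geometry
and conductivity are deliberately not trusted: their error is estimated as
the transfer-matrix perturbation ΔL. See `docs/methods.md` for the full
account.

## Worked example

```python
import taview as tv

# a complete synthetic experiment: meshes, lead field, ground-truth TMP
# movie with atrium-first activation, clean + 20 dB noisy ECG
bundle = tv.default_small(seed=7)

# invert the noisy ECG and score against the known ground truth
result = tv.run_recovery_experiment(bundle=bundle, chain_seed=11,
                                    n_iter=2000, n_burn=500)
print({k: round(v, 3) for k, v in result.theta_posterior_mean.items()})
print("atrial ECG correlation (worst lead):", round(result.atrial_corr_min, 3))

# extract the atrial-only 12-lead ECG with a 90% credible band
atrial = tv.atrial_ecg(result.chain, bundle.L_coarse,
                       mode="posterior_band", fs=bundle.fs)
marks = tv.wave_landmarks(atrial.record)
print({lead: {w: round(m.time_ms) for w, m in d.items()}
       for lead, d in list(marks.items())[:3]})
```

Output (seed 7 bundle, chain seed 11):

```
{'k': 8.502, 'a': 0.153, 'e': 0.01}
atrial ECG correlation (worst lead): 0.997
{'I': {'P': 8, 'Ta': 130}, 'II': {'P': 8, 'Ta': 130}, 'III': {'P': 8, 'Ta': 130}}
```

The generating parameters were k = 8, a = 0.15, e = 0.01: the posterior means
land within a few percent, the extracted atrial ECG correlates ≥ 0.99 with
the true atrial projection in every lead, and the landmark report shows the
P wave at ~8 ms and the recovered Ta wave at ~130 ms — a deflection that is
invisible in the full ECG, where the ventricular QRS (paced at 120 ms after
the atria) overlaps it.

A command-line interface mirrors the library
(`taview mesh build`, `taview leadfield`, `taview simulate`, `taview forward`,
`taview preprocess`, `taview fixtures make`, `taview invert`,
`taview extract`); run `taview --help`.

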