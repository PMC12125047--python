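# lumiphantom

In-silico dosimetry of laser-induced cavitation in melanosome phantoms.

Short-pulsed (nanosecond) lasers treat pigmented skin lesions by disrupting
melanosomes; the clinical endpoint — immediate whitening from vacuolization
— is hard to relate to the depth at which the light response is actually
induced. `lumiphantom` re-implements, entirely in silico, the quantitative
chain that links irradiation parameters to cavitation depth in a
tissue-mimicking melanosome/Intralipid phantom:

1. **Monte Carlo photon transport** (`lumiphantom.mc`) — voxelized
   hop-drop-spin random walk with Henyey–Greenstein scattering, air/medium
   Fresnel boundaries and a track-length fluence tally, for a normally
   incident circular top-hat beam. Produces relative fluence maps
   φ(r, z) = F(r, z)/F₀ and slab reflectance/transmittance observables.
2. **Inverse Monte Carlo** (`lumiphantom.inversion`) — recovers (μa, μs)
   from slab R/T with fixed (g, n) by derivative-free minimization over
   (log μa, log μs) with common random numbers, emulating
   integrating-sphere phantom characterization.
3. **Synthetic phantom imagery** (`lumiphantom.synth`) — pre/post
   irradiation cross-section images whose cavity-covered area fraction at
   local fluence x follows the logistic dose-response
   y = L / (1 + exp(−k(x − x₀))) + b, the stand-in for the wet-lab
   experiment.
4. **Cavity segmentation** (`lumiphantom.extraction`) — the local-mean
   brightness rule (≥ +10 gray levels over the mean within r = 0.1 mm),
   pre-irradiation size filtering, and the 0.19-mm surface-band exclusion.
5. **Dose-response estimation** (`lumiphantom.dose_response`) — centroid
   registration of masks onto fluence slices, cavitation ratio per
   0.1-J/cm² in-phantom fluence bin, per-fluence range pooling, and the
   least-squares logistic fit whose inflection x₀ is the cavitation-onset
   threshold fluence.
6. **Depth prediction** (`lumiphantom.depth`) — the deepest on-axis depth
   where fluence still reaches a threshold, and cavitation-ratio-vs-depth
   profiles for varying spot size and irradiation fluence.

The phantom optics used throughout are μa = 0.348 mm⁻¹, μs′ = 2.81 mm⁻¹,
g = 0.86, n = 1.4 at 532 nm; irradiation conditions are 2/3/4/5 J/cm² with
2/3/5-mm top-hat spots.

## Worked example

```python
import lumiphantom as lp
from lumiphantom.pipeline import run_full_pipeline

res = run_full_pipeline({
    "beam": {"spot_mm": 2.0},
    "mc": {"n_photons": 2_000_000, "seed": 5},
})
fit = res["summary"]["sigmoid_fit"]["params"]
print({k: round(v, 3) for k, v in fit.items()})
for row in res["summary"]["threshold_depths_mm"][:3]:
    print(row)
```

prints (images are synthesized with the generating parameters
L = 0.24, x₀ = 1.37, k = 2.0, b = −0.005):

```
{'L': 0.233, 'x0': 1.388, 'k': 1.982, 'b': -0.005}
{'spot_mm': 2.0, 'fluence_Jcm2': 2.0, 'depth_mm': 0.8070799891414121}
{'spot_mm': 3.0, 'fluence_Jcm2': 2.0, 'depth_mm': 0.916037983455483}
{'spot_mm': 5.0, 'fluence_Jcm2': 2.0, 'depth_mm': 0.9837579172943475}
```

The fitted curve recovers the generating dose-response: the threshold
fluence comes back at 1.39 J/cm² (truth 1.37) and the saturation ratio at
0.23 (truth 0.24). The threshold depths show the central prediction: at
fixed irradiation fluence, larger spots drive cavitation deeper
(0.81 → 0.92 → 0.98 mm for 2 → 3 → 5 mm spots at 2 J/cm²).

The same pipeline is available from a shell:

```
lumiphantom run --out results/ --seed 5
lumiphantom invert --measurement slab.json --out props.json
```

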