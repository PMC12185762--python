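# epimech

Vertex-model mechanics of ciliated epithelia, with the analysis toolkit for
macropinocytosis-driven apical remodeling.

Developing epithelia (e.g. the *Xenopus* embryo epidermis) relieve
proliferation-induced crowding not only by extruding whole cells but by
shrinking apical surfaces through macropinocytosis — large actin-ruffle
engulfment events that internalise ~10% of a cell's apical area in ~9 min.
Multiciliated cells (MCCs), which are stiff and never divide, locally
concentrate this crowding: their neighbours organise into rosettes and carry
distinctive mechanical stress.  `epimech` provides, as a single tested
package:

- a **vertex-model simulator** of a proliferating monolayer with embedded
  stiff, non-dividing MCCs, built on signed incidence matrices (`B·A = 0`)
  with a logarithmic force–strain law
  (`p = −σ ln(A/A0)`, `t = σΓ ln(L/L0)`), overdamped relaxation, cell
  division, T1 exchanges and the 61 → 400 → 800-cell experiment protocol;
- **stress statistics**: per-cell stress tensors, effective pressure /
  tension / shear, and the MCC-neighbourhood decile-enrichment analysis with
  paired t-tests across replicate simulations;
- **junction-tension inference** (CellFIT-style force balance at triple
  junctions, tensions relative, mean-normalised) with N1–N4 ring labels and
  before/after event ratios;
- **event analytics** for macropinocytosis tables and cell/junction tracks:
  onset-synchronised area traces, loss/size correlation, junction
  shortening, events-per-cell-per-hour by MCC adjacency, log2 fold changes,
  a tissue remodeling index, and post-extrusion neighbourhood rates;
- **synthetic-data generators** for segmented-tissue geometry, exact
  known-tension junction networks (the inference oracle), and event/track
  tables with the measured statistical structure (duration 9.3 ± 2.3 min,
  peak area 94 ± 36 µm², ~10% apical loss, r² ≈ 0.4 loss/size coupling,
  10% junction shortening, compression waves with ≥80% cell participation).

## Worked example

Run a scaled ensemble of the MCC experiment (10 replicates of the
37 → 100 → 200-cell profile with σ = 10 stiff MCCs) and test the
neighbourhood enrichment:

```python
from epimech.protocol import ProtocolConfig, run_ensemble
from epimech.stress import enrichment_report

cfg = ProtocolConfig.scaled(sigma_mcc=10.0, base_seed=100)
ensemble = run_ensemble(cfg)
fractions, tests = enrichment_report(ensemble)
print(tests.round(4).to_string(index=False))
```

```
            metric    tail  mean_adjacent  mean_non_adjacent      t      p  n
effective_pressure  lowest        14.5623             8.5650 2.6284 0.0274 10
           tension  lowest        15.1228             8.3753 2.5860 0.0294 10
             shear highest        16.3904             8.0177 2.8568 0.0189 10
```

Reading: in an unbiased tissue each group would put 10% of its cells in any
decile.  MCC-adjacent cells are instead ~15% in the lowest decile of
effective pressure (most compressed), ~15% in the lowest decile of cortical
tension, and ~16% in the highest decile of shear — versus ~8–9% for
non-adjacent cells — and each contrast is significant across the ten
replicates (two-sided paired t-test).  Stiff non-dividing cells squeeze
their rosette of neighbours.

Validate the junction-tension inference against an exactly solvable
geometry:

```python
import numpy as np
from epimech.synth import gen_known_tension_mesh
from epimech.tension import infer_tensions

net, truth = gen_known_tension_mesh(50, tension_cv=0.3, seed=0)
sol = infer_tensions(net)
ok = sol.solved
r = np.corrcoef(truth[ok], sol.tensions[ok])[0, 1]
print(f"junctions: {net.n_junctions}  solved: {ok.sum()}  "
      f"residual: {sol.residual_max:.2e}  r(true, inferred): {r:.4f}")
```

```
junctions: 117  solved: 116  residual: 1.36e-13  r(true, inferred): 1.0000
```

The same functionality is exposed on the command line (`epimech simulate`,
`ensemble`, `analyze-stress`, `infer-tension`, `analyze-events`,
`epimech synth tissue|events|wave|tension`); every run logs its resolved
configuration and seed, and identical invocations produce identical outputs.

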