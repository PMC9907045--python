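# gemvuln

Growth-dependent vulnerability detection in genome-scale metabolic
models. Given an SBML model (Levels 1/2/3, fbc supported), `gemvuln`
computes flux constraints consistent with a fraction γ of the maximal
growth rate via flux variability analysis (FVA) and derives from them the
classical vulnerability sets:

- **chokepoints** — unique producers/consumers of a metabolite, with the
  producer/consumer roles derived from the flux directions the bounds
  allow (a reversible reaction counts on both sides);
- **dead-end metabolites** — metabolites without any admissible producer
  or consumer;
- **dead / reversible / non-reversible** reaction partition from bounds;
- **essential reactions** — single-knockout FBA screen, plus the
  growth-dependent variant (knockout optimum below γ·μ_max; γ=1 gives
  the reactions essential for optimal growth);
- **blocked reactions** — zero flux at every steady state (FVA without a
  growth floor);
- a **γ sweep** tracking how all set sizes change over a grid of growth
  fractions, exported as XLSX/TSV and a standalone HTML report.

Two LP backends are available: GLPK (via optlang, default) and HiGHS
(via SciPy). A brute-force oracle (`gemvuln.fixtures.brute_force_sets`)
re-derives every set by literal evaluation on a second backend and backs
the test suite, together with a deterministic synthetic-network
generator (`make_fixture`).

## CLI

```bash
gemvuln report --model model.xml --gamma 0,0.5,0.99,1.0 --out report_dir --format xlsx --format html
gemvuln chokepoints --model model.xml --gamma 1.0
gemvuln essential   --model model.xml            # plain essentiality
gemvuln blocked     --model model.xml
gemvuln dem         --model model.xml --remove --out-model pruned.xml
gemvuln update-bounds --model model.xml --gamma 0.5 --out-model fva.xml
```

Common flags: `--objective ID` (override the SBML objective),
`--epsilon FLOAT` (zero tolerance, default 1e-6), `--solver glpk|scipy`,
`--include-boundary` (keep boundary metabolites in chokepoint/DEM
analysis). Exit codes: 0 success, 1 usage error, 2 model/solver error.

## Library

```python
from gemvuln import read_sbml, max_growth, growth_dependent_sets, run_sweep

model = read_sbml("model.xml")
ctx = max_growth(model, gamma=0.99)       # FBA for mu_max
report = growth_dependent_sets(model, ctx)  # sets of the FVA-constrained model
sweep = run_sweep(model, (0.0, 0.5, 1.0))
print(sweep.sizes())
```

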