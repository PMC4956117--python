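"""One-call pipeline: simulate -> describe -> design -> fit -> summarise.

Everything is driven by a single config mapping (YAML files work too); the
run directory gets the data, descriptive tables, chains, result CSVs and a
reproducibility manifest with a hash of every output file.
"""

import morbmap as m

config = m.validate_config(
    {
        "seed": 11,
        "out_dir": "scratch/example_run",
        "source": {"kind": "synthetic", "profile": "edhs_like", "n_children": 3000},
        "model": {"n_iterations": 1500, "burn_in": 500, "thinning": 2},
    }
)
manifest = m.run_pipeline(config)

print("stages completed:", ", ".join(manifest["stages"]))
print("records:", manifest["stages"]["data"]["n_records"])
print("posterior draws:", manifest["stages"]["mcmc"]["n_draws"])
print("output files hashed in manifest:", len(manifest["files"]))
print("\nRe-running with the same config and seed reproduces the manifest")
print("byte-for-byte; see scratch/example_run/results/ for the OR and")
print("spatial-effect tables per comorbidity category.")
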