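"""Run the full pipeline end to end and print its summary report.

Writes all stage tables (sample sheet, beta matrix, clock model and
predictions, DMP table, probe annotation, region/element enrichments, gene
directions, overlaps) plus summary.json into one run directory; a rerun
with the same seed reproduces every table byte for byte.
"""

from hibernaclock import PipelineConfig, SyntheticConfig, run_pipeline, summarize

config = PipelineConfig(synthetic=SyntheticConfig(seed=11), seed=11,
                        n_perm=200)
run_dir = run_pipeline(config, "pipeline_demo")
print(summarize(run_dir)["text"])
print(f"\nstage outputs written to {run_dir}/")
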