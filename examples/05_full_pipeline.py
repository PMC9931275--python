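"""One-call reproduction: cohort -> agreement -> metrics -> reliability.

run_all writes every result table as CSV into one directory plus a
manifest.json of SHA-256 hashes; identical (config, seed) always produce
identical hashes, so a run is fully reproducible from its config.
"""

from sleepval import RunConfig, run_all

manifest = run_all(RunConfig(seed=42, output_dir="pipeline_out", log_level="WARNING"))
print(f"{len(manifest)} artifacts in pipeline_out/:")
for name, digest in manifest.items():
    print(f"  {name:<32} sha256:{digest[:12]}...")
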