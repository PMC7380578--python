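.PHONY: test fixtures

test:
	python -m pytest -q tests/

# regenerate the synthetic example datasets from fixed seeds
fixtures:
	mkdir -p data-generated
	python -m fluxtherm.cli synth --model tsac-core --seed 1 \
	    --out data-generated/tsac-core-seed1.csv
	python -m fluxtherm.cli synth --model cthe-core+me --seed 1 \
	    --out data-generated/cthe-core-seed1.csv
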