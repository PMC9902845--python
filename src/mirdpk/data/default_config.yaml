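# Default pipeline configuration.
# Any subset may be overridden by a user config passed via --config.
nuclide:
  name: Cu-64
  half_life_h: 12.7
void_interval_h: 2.0
model: auto            # mono | bi | auto
times_in_minutes: false
region_aliases: {}     # extra region-name aliases, e.g. {bm: red_marrow}
simulate:
  n: 9
  cv: 0.05
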