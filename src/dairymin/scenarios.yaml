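# Scenario presets for the requirement calculators.
# comparison_grid: milk yields with the standard forage schedule; BW is
# interpolated 500 kg @ 10 kg/d -> 700 kg @ 50 kg/d, DMI 20.7 @ 30 -> 27.0 @ 50.
# worked_examples: the two desk scenarios quoted in the package README.
comparison_grid:
  - {milk_yield: 10, forage_frac: 0.80}
  - {milk_yield: 20, forage_frac: 0.60}
  - {milk_yield: 30, forage_frac: 0.50}
  - {milk_yield: 40, forage_frac: 0.45}
  - {milk_yield: 50, forage_frac: 0.40}
worked_examples:
  - {mineral: P, bw: 700, milk_yield: 50, breed: Holstein, dmi: 27.0, forage_frac: 0.40}
  - {mineral: P, bw: 600, milk_yield: 30, breed: Holstein, dmi: 20.7, forage_frac: 0.50}
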