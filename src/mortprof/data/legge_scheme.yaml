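# Default 7-class cattle age scheme (ordinal classes over months of age).
# The terminal class is open-ended; `nominal_terminal_duration_months`
# is the finite length substituted for it when a tooth's admissible run
# must be split proportionally to class durations.
classes:
  - {label: "0-6m",   start_months: 0,  end_months: 6}
  - {label: "6-15m",  start_months: 6,  end_months: 15}
  - {label: "15-26m", start_months: 15, end_months: 26}
  - {label: "26-36m", start_months: 26, end_months: 36}
  - {label: "3-6y",   start_months: 36, end_months: 72}
  - {label: "6-8y",   start_months: 72, end_months: 96}
  - {label: ">8y",    start_months: 96, end_months: null}
terminal_open: true
nominal_terminal_duration_months: 24
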