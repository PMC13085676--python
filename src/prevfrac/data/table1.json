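{
 "strata": [
  {"label": "0",
   "arms": {"0": {"mass": 0.25, "risk_factual": 0.50, "risk_set1": 0.30},
            "1": {"mass": 0.25, "risk_factual": 0.30}}},
  {"label": "1",
   "arms": {"0": {"mass": 0.15, "risk_factual": 0.30, "risk_set1": 0.20},
            "1": {"mass": 0.15, "risk_factual": 0.20}}},
  {"label": "2",
   "arms": {"0": {"mass": 0.10, "risk_factual": 0.16, "risk_set1": 0.12},
            "1": {"mass": 0.10, "risk_factual": 0.12}}}
 ],
 "meta": {
  "name": "hypothetical-trial",
  "description": "Marginally randomized trial of a preventive treatment with enrolment dependent on a three-level effect modifier M; worse-prognosis strata (M=0,1) were prioritized for recruitment.",
  "assumptions": [
   "Pr(Y^0=1|A=1,M=m) is not given by the scenario; exchangeability within levels of M (which holds for a marginally randomized trial by weak union) pins it to the arm-0 factual risk, and this fixture adopts that.",
   "The joint of (Y^0, Y^1) within each cell is completed from its margins by the monotone (no-one-harmed) coupling; caseload measures depend only on the margins."
  ]
 }
}
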