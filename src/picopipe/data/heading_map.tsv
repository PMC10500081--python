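# Common structured-abstract headings mapped to raw section categories.
# Categories: background, objective, methods, results, conclusions
# (objective is folded into background downstream).
BACKGROUND	background
INTRODUCTION	background
CONTEXT	background
RATIONALE	background
IMPORTANCE	background
OBJECTIVE	objective
OBJECTIVES	objective
AIM	objective
AIMS	objective
PURPOSE	objective
GOAL	objective
GOALS	objective
HYPOTHESIS	objective
STUDY OBJECTIVE	objective
METHODS	methods
METHOD	methods
METHODOLOGY	methods
DESIGN	methods
STUDY DESIGN	methods
DESIGN AND METHODS	methods
MATERIALS AND METHODS	methods
PATIENTS AND METHODS	methods
SUBJECTS AND METHODS	methods
METHODS AND RESULTS	methods
SETTING	methods
PARTICIPANTS	methods
PATIENTS	methods
SUBJECTS	methods
POPULATION	methods
INTERVENTION	methods
INTERVENTIONS	methods
EXPOSURE	methods
PROCEDURES	methods
MEASUREMENTS	methods
OUTCOME MEASURES	methods
MAIN OUTCOME MEASURES	methods
MAIN OUTCOME MEASURE	methods
STATISTICAL ANALYSIS	methods
DATA SOURCES	methods
RESULTS	results
FINDINGS	results
MAIN RESULTS	results
OUTCOMES	results
MAIN FINDINGS	results
CONCLUSIONS	conclusions
CONCLUSION	conclusions
INTERPRETATION	conclusions
DISCUSSION	conclusions
CLINICAL IMPLICATIONS	conclusions
SIGNIFICANCE	conclusions
RELEVANCE	conclusions
CONCLUSIONS AND RELEVANCE	conclusions
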