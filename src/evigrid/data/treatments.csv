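concept_id,name
101,amitriptyline
102,bupropion
103,citalopram
104,desvenlafaxine
105,doxepin
106,duloxetine
107,electroconvulsive therapy
108,escitalopram
109,fluoxetine
110,mirtazapine
111,nortriptyline
112,paroxetine
113,psychotherapy
114,sertraline
115,trazodone
116,venlafaxine
117,vilazodone
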