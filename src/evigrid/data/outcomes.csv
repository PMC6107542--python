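concept_id,name
201,acute liver injury
202,acute myocardial infarction
203,alopecia
204,constipation
205,decreased libido
206,delirium
207,diarrhoea
208,fracture
209,gastrointestinal haemorrhage
210,hyperprolactinaemia
211,hyponatraemia
212,hypotension
213,hypothyroidism
214,insomnia
215,nausea
216,open-angle glaucoma
217,seizure
218,stroke
219,suicide and suicidal ideation
220,tinnitus
221,ventricular arrhythmia and sudden cardiac death
222,vertigo
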