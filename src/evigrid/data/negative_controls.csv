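concept_id,name
301,acariasis
302,amyloidosis
303,ankylosing spondylitis
304,aseptic necrosis of bone
305,astigmatism
306,Bell's palsy
307,benign epithelial neoplasm of skin
308,chalazion
309,chondromalacia
310,Crohn's disease
311,croup
312,diabetic oculopathy
313,endocarditis
314,endometrial hyperplasia
315,enthesopathy
316,epicondylitis
317,Epstein-Barr virus disease
318,fracture of upper limb
319,gallstone
320,genital herpes simplex
321,haemangioma
322,Hodgkin's disease
323,human papilloma virus infection
324,hypoglycaemic coma
325,hypopituitarism
326,impetigo
327,ingrowing nail
328,iridocyclitis
329,irritable bowel syndrome
330,lesion of cervix
331,Lyme disease
332,malignant neoplasm of endocrine gland
333,mononeuropathy
334,onychomycosis
335,osteochondropathy
336,paraplegia
337,polyp of intestine
338,presbyopia
339,pulmonary tuberculosis
340,rectal mass
341,sarcoidosis
342,scar
343,seborrhoeic keratosis
344,septic shock
345,Sjogren's syndrome
346,Tietze's disease
347,tonsillitis
348,toxic goitre
349,ulcerative colitis
350,viral conjunctivitis
351,viral hepatitis
352,visceroptosis
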