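word,transcription,stress_syllable,pos,valence_mean,valence_sd,arousal_mean,arousal_sd
general,x e . n e . ɾ a l,3,adjective,5.8,1.1,4.6,1.2
panel,p a . n e l,2,noun,5.1,0.9,4.2,1.0
huir,u . i ɾ,2,verb,3.2,1.3,6.4,1.2
canal,k a . n a l,2,noun,5.4,0.8,4.4,1.1
colateral,k o . l a . t e . ɾ a l,4,adjective,4.6,1.0,4.8,1.2
craneal,k ɾ a . n e . a l,3,adjective,4.9,1.1,4.5,1.3
peral,p e . ɾ a l,2,noun,5.9,0.9,3.6,1.0
coronel,k o . ɾ o . n e l,3,noun,5.0,1.2,4.9,1.2
poligonal,p o . l i . g o . n a l,4,adjective,5.0,0.8,4.1,1.0
elemental,e . l e . m e n . t a l,4,adjective,5.6,0.9,4.0,1.1
unilateral,u . n i . l a . t e . ɾ a l,5,adjective,4.5,1.1,4.6,1.2
tifus,t i . f u s,1,noun,2.4,1.2,6.2,1.3
hepatitis,e . p a . t i . t i s,3,noun,2.2,1.1,6.3,1.3
faringitis,f a . ɾ i n . x i . t i s,3,noun,2.5,1.0,5.9,1.2
meningitis,m e . n i n . x i . t i s,3,noun,1.8,1.0,6.8,1.2
conjuntivitis,k o n . x u n . t i . b i . t i s,4,noun,2.6,1.1,5.8,1.3
apendicitis,a . p e n . d i . θ i . t i s,4,noun,2.3,1.1,6.5,1.2
cruel,k ɾ u e l,1,adjective,2.0,1.2,6.6,1.3
local,l o . k a l,2,adjective,5.3,0.8,4.3,1.0
laurel,l a u . ɾ e l,2,noun,6.0,0.9,3.8,1.0
mesa,m e . s a,1,noun,5.5,0.7,3.5,0.9
perro,p e . r o,1,noun,6.8,1.2,5.2,1.3
año,a . ɲ o,1,noun,5.9,0.9,4.4,1.1
calle,k a . ʎ e,1,noun,5.2,0.8,4.7,1.1
chico,tʃ i . k o,1,noun,6.1,0.9,4.8,1.1
guerra,g e . r a,1,noun,1.5,0.9,7.8,1.1
zorro,θ o . r o,1,noun,5.7,1.0,4.9,1.2
huevo,w e . β o,1,noun,6.2,0.8,3.9,1.0
yegua,ʝ e . g w a,1,noun,5.8,0.9,4.3,1.1
jamón,x a . m o n,2,noun,7.0,1.0,4.6,1.2
fatal,f a . t a l,2,adverb,1.9,1.1,6.9,1.2
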