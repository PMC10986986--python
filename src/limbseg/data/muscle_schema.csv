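class_id,name,abbreviation,section,included
1,adductor brevis,AB,hips,1
2,adductor longus,AL,hips,1
3,adductor magnus,AM,hips,1
4,biceps femoris caput breve,BFCB,thigh,1
5,biceps femoris caput longum,BFCL,thigh,1
6,extensor digitorum longus,,calf,0
7,extensor hallucis longus,,calf,0
8,flexor digitorum longus,,calf,0
9,flexor hallucis longus,,calf,0
10,gastrocnemius lateralis,GL,calf,1
11,gastrocnemius medialis,GM,calf,1
12,gemellus superior,,hips,0
13,gluteus maximus,GLM,hips,1
14,gluteus medius,,hips,0
15,gluteus minimus,,hips,0
16,gracilis,GR,thigh,1
17,iliacus,IL,hips,1
18,obturator externus,,hips,0
19,obturator internus,,hips,0
20,pectineus,,hips,0
21,peroneus brevis,PB,calf,1
22,peroneus longus,PL,calf,1
23,piriformis,,hips,0
24,popliteus,,calf,0
25,psoas,,hips,0
26,quadratus femoris,,hips,0
27,rectus femoris,RF,thigh,1
28,sartorius,SA,thigh,1
29,semimembranosus,SB,thigh,1
30,semitendinosus,ST,thigh,1
31,soleus,S,calf,1
32,tensor fasciae latae,TFL,thigh,1
33,tibialis anterior,TA,calf,1
34,tibialis posterior,TP,calf,1
35,vastus intermedius,VI,thigh,1
36,vastus lateralis,VL,thigh,1
37,vastus medialis,VM,thigh,1
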