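unit,category,synonyms,anchors
boy,subject,boy|son,boy
girl,subject,girl|daughter,girl
woman,subject,woman|mother|lady,woman|mother
kitchen,place,kitchen,kitchen
window,place,window,window
curtains,place,curtain,curtain
sink,place,sink,sink
cupboard,place,cupboard|cabinet,cupboard
exterior,place,outside|garden|yard,garden|outside
cookie,object,cookie|biscuit,cookie
jar,object,jar,jar
stool,object,stool,stool
water,object,water,water
dishes,object,dish,dish
plate,object,plate,plate
dishcloth,object,dishcloth|towel|cloth,towel
taking,action,take|steal|grab,take|steal
falling,action,fall|tip|wobble,fall
washing,action,wash|dry|wipe,wash
overflow,action,overflow|spill,overflow|spill
asking,action,ask,ask
unconcerned,action,unconcerned|oblivious|distracted,unconcerned
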