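{
 "_comment": "Synthetic hand-built lexical knowledge base: a small hypernym DAG with per-word sense inventories (frequency order) and noun-sense synonym sets. Stands in for a full lexical database so the resolvers are testable offline; includes the plant/flower case whose lowest common hypernym is the overly broad 'whole', a known quirk of the large resource this mirrors.",
 "synonyms": {
  "automobile": ["car", "auto"],
  "bicycle": ["bike"],
  "bike": ["bicycle"],
  "car": ["automobile", "auto"],
  "cat": ["feline"],
  "couch": ["sofa"],
  "rabbit": ["bunny"],
  "sofa": ["couch"],
  "television": ["tv", "telly"],
  "tv": ["television", "telly"]
 },
 "senses": {
  "animal": [["animal.n.01", "n"]],
  "asp": [["asp.n.01", "n"]],
  "automobile": [["car.n.01", "n"]],
  "ball": [["ball.n.01", "n"], ["ball.v.01", "v"]],
  "bed": [["bed.n.01", "n"], ["bed.v.01", "v"]],
  "big": [["big.a.01", "a"]],
  "bird": [["bird.n.01", "n"]],
  "bowl": [["bowl.n.01", "n"], ["bowl.v.01", "v"]],
  "bread": [["bread.n.01", "n"]],
  "bunny": [["rabbit.n.01", "n"]],
  "cake": [["cake.n.01", "n"]],
  "canine": [["canine.n.01", "n"]],
  "car": [["car.n.01", "n"]],
  "cat": [["cat.n.01", "n"]],
  "chair": [["chair.n.01", "n"]],
  "cheese": [["cheese.n.01", "n"]],
  "church": [["church.n.01", "n"]],
  "couch": [["sofa.n.01", "n"], ["couch.v.01", "v"]],
  "cross": [["cross.v.01", "v"], ["cross.n.01", "n"]],
  "doberman": [["doberman.n.01", "n"]],
  "dog": [["dog.n.01", "n"], ["dog.v.01", "v"]],
  "entity": [["entity.n.01", "n"]],
  "father": [["father.n.01", "n"]],
  "feline": [["feline.n.01", "n"]],
  "flower": [["flower.n.01", "n"]],
  "food": [["food.n.01", "n"]],
  "furniture": [["furniture.n.01", "n"]],
  "horse": [["horse.n.01", "n"]],
  "lion": [["lion.n.01", "n"]],
  "organism": [["organism.n.01", "n"]],
  "parrot": [["parrot.n.01", "n"], ["parrot.v.01", "v"]],
  "pig": [["pig.n.01", "n"]],
  "plant": [["plant.n.01", "n"], ["plant.v.01", "v"]],
  "poodle": [["poodle.n.01", "n"]],
  "rabbit": [["rabbit.n.01", "n"]],
  "reptile": [["reptile.n.01", "n"]],
  "robin": [["robin.n.01", "n"]],
  "snake": [["snake.n.01", "n"], ["snake.v.01", "v"]],
  "sofa": [["sofa.n.01", "n"]],
  "table": [["table.n.01", "n"]],
  "tabby": [["tabby.n.01", "n"]],
  "television": [["television.n.01", "n"]],
  "truck": [["truck.n.01", "n"]],
  "tv": [["television.n.01", "n"]],
  "vehicle": [["vehicle.n.01", "n"]],
  "whole": [["whole.n.01", "n"], ["whole.a.01", "a"]]
 },
 "synsets": {
  "animal.n.01": {"lemmas": ["animal", "beast", "creature"], "parents": ["organism.n.01"]},
  "asp.n.01": {"lemmas": ["asp"], "parents": ["snake.n.01"]},
  "ball.n.01": {"lemmas": ["ball"], "parents": ["entity.n.01"]},
  "bed.n.01": {"lemmas": ["bed"], "parents": ["furniture.n.01"]},
  "bird.n.01": {"lemmas": ["bird"], "parents": ["animal.n.01"]},
  "bowl.n.01": {"lemmas": ["bowl"], "parents": ["entity.n.01"]},
  "bread.n.01": {"lemmas": ["bread"], "parents": ["food.n.01"]},
  "cake.n.01": {"lemmas": ["cake"], "parents": ["food.n.01"]},
  "canine.n.01": {"lemmas": ["canine", "canid"], "parents": ["animal.n.01"]},
  "car.n.01": {"lemmas": ["car", "automobile", "auto"], "parents": ["vehicle.n.01"]},
  "cat.n.01": {"lemmas": ["cat", "feline"], "parents": ["feline.n.01"]},
  "chair.n.01": {"lemmas": ["chair"], "parents": ["furniture.n.01"]},
  "cheese.n.01": {"lemmas": ["cheese"], "parents": ["food.n.01"]},
  "church.n.01": {"lemmas": ["church"], "parents": ["entity.n.01"]},
  "cross.n.01": {"lemmas": ["cross"], "parents": ["entity.n.01"]},
  "doberman.n.01": {"lemmas": ["doberman", "doberman_pinscher"], "parents": ["dog.n.01"]},
  "dog.n.01": {"lemmas": ["dog", "domestic_dog"], "parents": ["canine.n.01"]},
  "entity.n.01": {"lemmas": ["entity"], "parents": []},
  "father.n.01": {"lemmas": ["father"], "parents": ["entity.n.01"]},
  "feline.n.01": {"lemmas": ["feline", "felid"], "parents": ["animal.n.01"]},
  "flower.n.01": {"lemmas": ["flower", "bloom"], "parents": ["angiosperm.n.01"]},
  "angiosperm.n.01": {"lemmas": ["angiosperm"], "parents": ["whole.n.01"]},
  "food.n.01": {"lemmas": ["food"], "parents": ["entity.n.01"]},
  "furniture.n.01": {"lemmas": ["furniture"], "parents": ["entity.n.01"]},
  "horse.n.01": {"lemmas": ["horse", "equus_caballus"], "parents": ["animal.n.01"]},
  "lion.n.01": {"lemmas": ["lion"], "parents": ["feline.n.01"]},
  "organism.n.01": {"lemmas": ["organism", "being"], "parents": ["entity.n.01"]},
  "parrot.n.01": {"lemmas": ["parrot"], "parents": ["bird.n.01"]},
  "pig.n.01": {"lemmas": ["pig", "hog", "swine"], "parents": ["animal.n.01"]},
  "plant.n.01": {"lemmas": ["plant", "flora"], "parents": ["whole.n.01"]},
  "poodle.n.01": {"lemmas": ["poodle"], "parents": ["dog.n.01"]},
  "rabbit.n.01": {"lemmas": ["rabbit", "bunny"], "parents": ["animal.n.01"]},
  "reptile.n.01": {"lemmas": ["reptile"], "parents": ["animal.n.01"]},
  "robin.n.01": {"lemmas": ["robin"], "parents": ["bird.n.01"]},
  "snake.n.01": {"lemmas": ["snake", "serpent"], "parents": ["reptile.n.01"]},
  "sofa.n.01": {"lemmas": ["sofa", "couch"], "parents": ["furniture.n.01"]},
  "table.n.01": {"lemmas": ["table"], "parents": ["furniture.n.01"]},
  "tabby.n.01": {"lemmas": ["tabby"], "parents": ["cat.n.01"]},
  "television.n.01": {"lemmas": ["television", "tv", "telly"], "parents": ["entity.n.01"]},
  "truck.n.01": {"lemmas": ["truck"], "parents": ["vehicle.n.01"]},
  "vehicle.n.01": {"lemmas": ["vehicle"], "parents": ["entity.n.01"]},
  "whole.n.01": {"lemmas": ["whole", "unit"], "parents": ["entity.n.01"]}
 }
}
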